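"""Quantify the five EZ biomarkers on a healthy and a degraded phantom.

Generates a noise-free healthy phantom and a disease-style phantom (EZ
shortened to +-1.5 mm and attenuated to 60% reflectance), runs the biomarker
panel on both, and prints the nasal-region values side by side.  On the
healthy phantom the peak distances and thickness recover the construction
geometry exactly; on the degraded phantom rEZI drops with the attenuation.
"""

from ezoct import PhantomSpec, generate_bscan
from ezoct.biomarkers import analyze_bscan

healthy = PhantomSpec(speckle_level=0.15)
disease = PhantomSpec(speckle_level=0.15, ez_extent_mm=1.5, ez_attenuation=0.6)

rows = {}
for label, spec in (("healthy", healthy), ("RPE65-IRD-like", disease)):
    image, mask = generate_bscan(spec, seed=3)
    rows[label] = analyze_bscan(image, mask)["nasal"]

fields = [
    ("OPL-EZ distance (um)", "opl_ez_um"),
    ("ELM-EZ distance (um)", "elm_ez_um"),
    ("EZ-BM distance (um)", "bm_ez_um"),
    ("ELM-BM distance (um)", "elm_bm_um"),
    ("EZ thickness (um)", "ez_thickness_um"),
    ("rEZI (%)", "rezi_percent"),
    ("EZ granularity (%)", "ez_tv_percent"),
]
print(f"{'biomarker':26s} {'healthy':>12s} {'degraded':>12s}")
for name, attr in fields:
    h = getattr(rows["healthy"], attr)
    d = getattr(rows["RPE65-IRD-like"], attr)
    print(f"{name:26s} {h:12.3f} {d:12.3f}")
print("\nrEZI (relative EZ intensity) falls with EZ attenuation; distances at")
print("0.5 mm nasal eccentricity are unchanged because the band geometry is.")
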