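"""Compare EZ biomarkers between a control and a patient phantom cohort.

Generates ground-truth biomarkers for 12 healthy and 12 degraded phantoms,
routes each comparison through a Shapiro-Wilk normality check (t test if both
groups look normal, Wilcoxon rank-sum otherwise), and screens the biomarker
table for Pearson correlations with r > 0.3.
"""

import numpy as np
import pandas as pd

from ezoct import PhantomSpec, generate_bscan
from ezoct.biomarkers import analyze_bscan
from ezoct.stats import compare_groups, correlation_screen

rows = []
rng = np.random.default_rng(0)
for cohort, n in (("control", 12), ("patient", 12)):
    for i in range(n):
        kw = {}
        if cohort == "patient":
            kw = dict(ez_extent_mm=float(rng.uniform(0.8, 2.0)),
                      ez_attenuation=float(rng.uniform(0.4, 0.8)))
        spec = PhantomSpec(speckle_level=0.25, **kw)
        image, mask = generate_bscan(spec, seed=int(rng.integers(2**31)))
        rec = analyze_bscan(image, mask)["nasal"]
        rows.append({"cohort": cohort, **{k: v for k, v in rec.as_dict().items()
                                          if isinstance(v, float)}})
table = pd.DataFrame(rows)

print(f"{'biomarker':18s} {'control':>16s} {'patient':>16s} {'test':>9s} {'p':>10s}")
for col in ("rezi_percent", "ez_tv_percent", "ez_thickness_um", "opl_ez_um", "elm_bm_um"):
    a = table[table.cohort == "control"][col]
    b = table[table.cohort == "patient"][col]
    res = compare_groups(a, b, biomarker=col)
    print(f"{col:18s} {res.mean_a:8.2f}±{res.sd_a:6.2f} {res.mean_b:8.2f}±{res.sd_b:6.2f} "
          f"{res.test:>9s} {res.p_value:10.2e}")

print("\ncorrelations with |r| above the 0.3 moderate-association flag:")
for rep in correlation_screen(table, columns=["rezi_percent", "ez_tv_percent",
                                              "ez_thickness_um", "opl_ez_um"]):
    if rep.flagged_moderate:
        print(f"  {rep.var_a} ~ {rep.var_b}: r = {rep.r:.3f} (n = {rep.n})")
# rEZI separates the cohorts sharply (the attenuation knob acts on it
# directly); the normality routing picks the rank-sum test whenever a
# Shapiro-Wilk p-value drops below 0.05.
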