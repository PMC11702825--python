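# ezoct — outer-retina SD-OCT analysis

`ezoct` quantifies the integrity of the **ellipsoid zone (EZ)** — the second
hyperreflective outer-retinal band in spectral-domain optical coherence
tomography (SD-OCT), whose loss tracks photoreceptor degeneration in inherited
retinal dystrophies such as *RPE65*-IRD — from B-scans and volume scans.  It is
aimed at retinal-imaging researchers who need objective, automated EZ
biomarkers rather than qualitative grading.

The toolkit covers the full analysis chain:

1. **Layer segmentation.** A compact four-level U-Net (16 base filters, 5×5
   kernels, batch normalization, leaky ReLU, max-pool encoder, transposed-conv
   decoder, ≈1.26 M parameters; implemented in NumPy with manual
   backpropagation) labels each pixel as background (0), EZ (1), OPL zone (2),
   ELM zone (3), or IZ+RPE+BM complex (4).  B-scans are tiled into 496 × 128
   patches with a 64-pixel overlap and the per-patch probabilities are averaged
   back together.  Training minimizes a combined loss
   `L = (1−λ)·L_Dice + λ·L_wCE` with smoothed (ε = 1) multi-class Dice and
   inverse-class-frequency cross-entropy weights.
2. **EZ biomarkers** per A-scan, from the segmentation:
   * weighted peak distances `OPL_EZ`, `ELM_EZ`, `BM_EZ`, `ELM_BM` — axial
     distances (µm) between layer intensity peaks and the Bruch's-membrane
     boundary, scaled by the axial resolution `Sy ≈ 3.5 µm/px`;
   * EZ thickness `EZ_Th = mean((Ll − Lu + 1) · Sy)` over EZ-bearing A-scans;
   * relative EZ intensity `rEZI = mean((P_EZ − P_OPL)/P_EZ) × 100 %`;
   * EZ granularity `EZ_TV`: after ROF total-variation denoising
     (`argmin_u ½‖u−f‖² + α·TV(u)`, α = 0.05), the normalized local variation
     `EZ_LV(x) = Σ_{|k|≤β} Σ_{y∈EZ(x)} |P(x+k,y) − P(x,y)|`, β = 3,
     summed and divided by `2βN`;
   * values sampled 0.5 mm nasal/temporal to the fovea (laterality-aware).
3. **En-face EZ mapping** over volume scans: per-B-scan EZ limits, linear
   interpolation between B-scans onto a square 121 µm²-pixel grid, EZ area in
   mm² inside a 6-mm ETDRS-style region of interest, EZ width as % of the ROI.
4. **Statistics**: Shapiro–Wilk-routed two-group tests (t test vs Wilcoxon
   rank-sum) and Pearson correlation screening with an r > 0.3 flag.
5. **Synthetic phantoms** with exact ground truth — layered outer retina,
   foveal pit, multiplicative speckle, disease-style EZ shortening and
   attenuation — so every stage is verifiable without clinical data.

## Worked example

```python
from ezoct import PhantomSpec, generate_bscan
from ezoct.biomarkers import analyze_bscan

spec = PhantomSpec(speckle_level=0.15)                      # healthy phantom
image, mask = generate_bscan(spec, seed=3)
record = analyze_bscan(image, mask)["nasal"]                 # 0.5 mm nasal locus
print(record.opl_ez_um, record.ez_thickness_um, record.rezi_percent)
```

Running `python examples/02_ez_biomarkers.py` (healthy vs degraded phantom,
EZ shortened to ±1.5 mm and attenuated to 60 %) prints:

```
biomarker                       healthy     degraded
OPL-EZ distance (um)            130.974      131.158
ELM-EZ distance (um)             41.447       41.632
EZ-BM distance (um)              56.553       56.368
ELM-BM distance (um)             98.000       98.000
EZ thickness (um)                17.500       17.500
rEZI (%)                         55.154       25.398
EZ granularity (%)               78.900       41.573
```

The peak distances recover the phantom's band geometry (note `ELM_BM =
ELM_EZ + BM_EZ` — the per-column additivity of ordered peak distances), and
rEZI/EZ granularity fall with the simulated EZ attenuation, the signature of
photoreceptor degeneration this toolkit is built to measure.  The other
examples cover phantom generation (`01`), en-face area against an analytic
ellipse (`03`), U-Net training (`04`), and cohort statistics (`05`).

A thin CLI mirrors the library: `ezoct simulate|train|segment|biomarkers|
enface|stats|run` (see `ezoct --help`); `ezoct run` executes the whole
pipeline on phantom data and writes all artifacts plus a provenance log.

## Layout

```
src/ezoct/
  phantom.py        synthetic layered-retina B-scans/volumes with ground truth
  segmentation/     U-Net, combined loss, patching, splitting, training, metrics
  biomarkers.py     peak distances, EZ thickness, rEZI, TV denoising, granularity
  enface.py         EZ limits, interpolation, area, width, ETDRS ROI
  stats.py          normality-routed tests, correlation screening
  io.py, pipeline.py, cli.py
docs/methods.md     model assumptions, parameter choices, limitations
examples/           one narrative script per capability
```
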