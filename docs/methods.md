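# Methods

## Problem and data model

SD-OCT renders the retina as a stack of cross-sections (B-scans); each column
of a B-scan is one axial reflectivity profile (A-scan).  In inherited retinal
degenerations the ellipsoid zone (EZ) — the second hyperreflective outer band —
attenuates, thins, and contracts toward the fovea.  This package measures that
process.  All rasters use row 0 = inner retina (vitreous side), columns =
A-scans, 0-based indices; intensities live in [0, 1] (rescaled from the source
bit depth on read).  Class coding is fixed: 0 background, 1 EZ, 2 OPL zone,
3 ELM zone, 4 IZ+RPE+BM complex.

## Synthetic phantoms

Because no public dataset accompanies this problem setting, the `phantom`
module generates B-scans with exact ground truth.  Four hyperreflective bands
(OPL, ELM, EZ, RPE complex) are placed at fixed center rows with fixed
thicknesses; reflectance across each band follows a raised cosine peaking at
the band center, which makes the per-A-scan intensity peak well defined,
interior, and — for odd thicknesses — unique.  A foveal pit is modeled as a
Gaussian-shaped outward bow applied equally to all outer bands, so inter-band
separations are constant across columns and the noise-free biomarkers are known
in closed form.  Speckle is multiplicative unit-mean gamma noise
(shape 1/level², scale level²), the standard first-order OCT speckle
surrogate; unit mean preserves band reflectances on average.  Disease is
emulated by two knobs: `ez_extent_mm` truncates the EZ band laterally and
`ez_attenuation` scales its reflectance.

Default geometry (496 × 768 px, 3.5 µm/px axial, 11.0 µm/px lateral so one
en-face pixel ≈ 121 µm²) puts the noise-free biomarkers at OPL_EZ 129.5 µm,
ELM_EZ 42 µm, BM_EZ 56 µm, ELM_BM 98 µm, EZ thickness 17.5 µm and rEZI 60 % —
the range reported for healthy adult outer retinas.  Raw reflectance values
(0.34/0.55/0.85/0.80 for OPL/ELM/EZ/RPE) are free parameters, not calibrated
to any scanner's units; only their contrast matters to rEZI.  `compact_spec`
crops the field of view (e.g. 96 × 96) while preserving thicknesses and
separations, so small training phantoms carry the same µm-scale biomarkers.

What the phantoms do **not** model: photorealistic texture, inner-retina
layers, vessel shadows, motion/nystagmus artifacts, curvature of the retina,
and pathological disorganization beyond band truncation/attenuation.  Passing
tests therefore demonstrate correctness of the measurement chain on known
geometry, not clinical-grade segmentation performance.

## Segmentation network

A four-level U-Net: double 5×5 convolution blocks with batch normalization and
leaky ReLU (slope 0.1) at 16/32/64/128 filters, 2×2 max-pool downsampling, a
mirrored decoder with 2×2 stride-2 transposed convolutions and skip
concatenation, and a final 1×1 convolution onto 5 class channels (softmax).
The default configuration has 1,261,717 parameters.  The engine is written
directly in NumPy (channels-last; convolutions as per-offset BLAS matmuls;
manual backpropagation verified against central finite differences) and trains
with Adam.

The loss is `L = (1−λ)·L_Dice + λ·L_wCE`, λ = 0.5 by default.  The Dice term
is the smoothed multi-class soft Dice with ε = 1 in numerator and denominator
(so classes absent from a batch contribute ≈0 loss rather than 0/0); the
cross-entropy term weights pixels by class, defaulting to inverse class
frequency computed on the training set and normalized to mean 1 — the standard
remedy for the thin EZ/ELM bands, which occupy ~1–2 % of pixels.  λ and the
weights are exposed because no principled universal value exists; λ = 0.5
treats overlap and pixel-wise calibration symmetrically.

B-scans are tiled into 496 × 128 patches with a 64-px overlap (stride 64, so
11 patches for 768-wide and 15 for 1024-wide scans); the right edge is
reflect-padded when the width is not a stride multiple.  Stitching averages
overlapping probabilities and renormalizes — order-independent and idempotent
when patches agree; argmax ties break toward the lower class index.  Dataset
splits are by participant (all scans follow their participant) and stratified
by cohort, with per-cohort train counts rounded half-away-from-zero: a
94-control/22-patient roster at 80/20 yields 75 + 18 training and 19 + 4
validation participants.  Augmentation applies geometric transforms (flip,
small shift/scale; nearest-neighbor for labels) to both image and mask and
intensity transforms (gamma, brightness/contrast, additive noise) to the image
only.  Optimizer (Adam), learning rate (1e-3), epochs and batch size are
configuration values, not claims about any reference training recipe.

## Biomarkers

Per column, band limits `Lu`/`Ll` are the min/max row of each label; peaks are
intensity maxima within the band rows (ties to the smaller, inner row); the BM
boundary is the outermost row of the class-4 band.  Columns missing any
required layer are excluded from each biomarker's mean and reported in
`n_valid_columns` — atrophic retinas legitimately lose bands, and imputing
zeros would bias group means.

* **Weighted peak distances** are reported as magnitudes
  (`|Δrow| · Sy`, `Sy` = axial µm/px).  With magnitudes, an ordered stack
  (ELM above EZ above BM) satisfies `ELM_BM = ELM_EZ + BM_EZ` column by
  column, hence also in the means — the additivity invariant the tests check.
* **EZ thickness** uses the inclusive pixel count `Ll − Lu + 1`, so a
  one-pixel band measures one axial pixel (3.5 µm), not zero.
* **rEZI** is `(P_EZ − P_OPL)/P_EZ` in percent, sign preserved (negative when
  OPL outshines EZ); columns with `P_EZ = 0` are excluded.
* **EZ granularity**: the image is first TV-denoised (ROF model
  `½‖u−f‖² + α·TV(u)`, solved by Chambolle's dual projection via
  scikit-image; α maps one-to-one onto the ROF weight, verified against the
  1-D two-plateau closed form).  Then
  `EZ_LV(x) = Σ_{k=−β..β} Σ_{y∈EZ rows of x} |P(x+k,y) − P(x,y)|` with
  out-of-range neighbors skipped, and `EZ_TV = 100 · Σ_x EZ_LV / (2βN)`.
  `N` counts the EZ-bearing columns entering the sum: normalizing by all scan
  columns would make the statistic scale with scan width rather than EZ
  texture.  The per-column EZ row count is not divided out; the raw `EZ_LV`
  vector is returned so users can post-normalize by band height if desired.
  Defaults α = 0.05, β = 3 (β odd; the window is symmetric).
* **Regional sampling** takes mean ± SD over a ±0.1 mm window centered 0.5 mm
  nasal and temporal to the fovea.  The window width is a package choice (a
  single column would be noise-dominated).  Nasal is toward the optic disc:
  right of the fovea in left-eye scans, left of it in right-eye scans.

## En-face EZ area and width

Each B-scan contributes the outer envelope (min..max column) of its EZ label;
interior gaps within a B-scan are therefore bridged — a documented measurement
convention matching the two-limit formulation.  Limits are linearly
interpolated along the slow axis onto a square-pixel grid (default 11 µm
pitch ⇒ 121 µm²/pixel): gaps **between** EZ-bearing B-scans are filled,
EZ-free runs at the volume edge are left empty (interpolation, never
extrapolation).  EZ area is the tally of present pixels inside the region of
interest × pixel area.  The ROI defaults to the 6 × 6 mm square bounding the
ETDRS circle, with the 6-mm disc and the full ETDRS ring/quadrant grid
available; the square is the default because a healthy macular EZ footprint
regularly exceeds the 28.3 mm² disc, and a 6-mm-wide measurement region is
the square, not the disc, when reported areas run into the mid-30s of mm².
EZ width per B-scan is the span between the outermost EZ column centers
intersected with the ROI span, as % of the ROI diameter, clipped to [0, 100].
On a 61-B-scan volume with an elliptical footprint the tally recovers
π·a·b within 2 %; the error shrinks with B-scan spacing.

## Statistics

Group comparisons run Shapiro–Wilk on both samples; if both p > 0.05 a
two-sided two-sample t test is used (Welch form by default — equal variances
are not assumed; a flag restores the pooled form), otherwise the Wilcoxon
rank-sum test (exact enumeration when both n ≤ 20 and no ties, otherwise the
continuity-corrected normal approximation).  Samples below n = 3 are rejected:
the normality test is undefined there.  No multiple-testing correction is
applied; raw p-values are reported per biomarker/region.  Pearson screening
uses complete cases per pair, reports undefined r for zero-variance variables,
and flags signed r > 0.3 (negative correlations are reported with a note but
never flagged).  The routed procedure's type-I error is calibrated within
±0.02 of the nominal 0.05 over 2,000 null replicates at n = 50.

## Numerical choices and problem sizes

* Float32 network arithmetic (float64 option used by the gradient tests);
  softmax/loss in float64.
* TV denoising stopping tolerance 1e-6 on the relative cost decrease, capped
  at 500 iterations by default (tests requiring the 1-D closed form tighten
  both).
* Peak ties, argmax ties, and pooling ties all break deterministically toward
  the smaller index.
* Degenerate inputs (no EZ anywhere, zero valid columns) raise rather than
  return 0, so absence of signal is never confused with a zero measurement.
* Tests and the acceptance script train on compact 96 × 96 phantoms (200
  patches, 6 epochs, batch 8), the size at which the network comfortably
  exceeds EZ Dice 0.8 on 20 held-out phantoms while the whole run stays in the
  minutes range on a single CPU; the architecture itself is the full-size one.

## Known limitations

* The U-Net runs on CPU via NumPy; it is suitable for the phantom scale and
  for method validation, not for high-throughput clinical training runs.
* Phantom realism is deliberately minimal (see above); segmentation accuracy
  on phantoms does not predict clinical Dice.
* The granularity normalization (`2βN`, no band-height term) follows the
  printed definition of the statistic; records carry enough information to
  re-normalize.
* Proprietary scanner containers (.vol/.e2e, DICOM-OPT) are out of scope;
  rasters plus JSON sidecars are the interchange format.
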