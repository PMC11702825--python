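"""Per-A-scan intensity-profile analysis and the five EZ biomarkers.

From a segmented B-scan this module derives, per A-scan (column):

* **Weighted peak distances** — axial distances in µm between the intensity
  peaks of OPL, ELM and EZ and the BM boundary (the outermost pixel of the
  IZ+RPE+BM band), scaled by the axial resolution ``Sy`` (~3.5 µm/pixel):
  OPL_EZ, ELM_EZ, BM_EZ, ELM_BM.  Distances are reported as magnitudes; for
  a healthy stack ordered ELM < EZ < BM this makes ELM_BM = ELM_EZ + BM_EZ
  hold column by column.
* **EZ thickness** — mean over EZ-bearing columns of the inclusive band height
  (lower − upper + 1 pixels) times ``Sy``, so a one-pixel band has thickness
  ``Sy`` rather than zero.
* **rEZI** — relative EZ intensity, mean of (peak EZ − peak OPL)/peak EZ,
  in percent; negative when OPL outshines EZ.
* **EZ granularity (EZ_TV)** — after ROF total-variation denoising with
  smoothing parameter α, the local variation of the EZ band
  ``EZ_LV(x) = Σ_{k=-β..β} Σ_{y in EZ rows of x} |P(x+k, y) - P(x, y)|``
  summed over EZ-bearing columns and normalized by ``2 β N`` (N = number of
  columns entering the sum), in percent of the [0, 1] intensity scale.
  Defaults α = 0.05, β = 3.

Columns missing a required layer are excluded from each biomarker's mean and
counted, since atrophic retinas legitimately lose outer bands.  Regional values
are sampled 0.5 mm nasal and temporal to the fovea (window ±0.1 mm), with
nasal/temporal resolved from eye laterality.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
from skimage.restoration import denoise_tv_chambolle

from .phantom import BScanImage, ClassMap, LABELS

__all__ = [
    "LayerBands",
    "PeakTable",
    "BiomarkerRecord",
    "extract_layer_bands",
    "locate_peaks",
    "weighted_peak_distances",
    "ez_thickness",
    "rezi",
    "tv_denoise",
    "ez_granularity",
    "sample_at_eccentricity",
    "analyze_bscan",
]

_PEAK_CLASSES = ("opl", "elm", "ez")


@dataclass
class LayerBands:
    """Per-column upper/lower rows of each labeled band (classes 1–4).

    ``upper[c]``/``lower[c]`` are length-N integer arrays; ``present[c]`` flags
    columns where class ``c`` exists.  Rows are meaningless where absent.
    """

    upper: Dict[int, np.ndarray]
    lower: Dict[int, np.ndarray]
    present: Dict[int, np.ndarray]
    n_columns: int

    def band(self, name: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = LABELS[name]
        return self.upper[c], self.lower[c], self.present[c]


@dataclass
class PeakTable:
    """Per-column intensity peaks of OPL/ELM/EZ and the BM boundary row."""

    peak_row: Dict[str, np.ndarray]  # 'opl' | 'elm' | 'ez'
    peak_value: Dict[str, np.ndarray]
    bm_row: np.ndarray
    valid: np.ndarray  # all of OPL, ELM, EZ, RPE-complex present
    n_columns: int


@dataclass
class BiomarkerRecord:
    """One row of biomarker output for a scan region (means ± SD)."""

    region: str  # 'nasal' | 'temporal' | 'full-scan'
    opl_ez_um: float = float("nan")
    opl_ez_sd: float = float("nan")
    elm_ez_um: float = float("nan")
    elm_ez_sd: float = float("nan")
    bm_ez_um: float = float("nan")
    bm_ez_sd: float = float("nan")
    elm_bm_um: float = float("nan")
    elm_bm_sd: float = float("nan")
    ez_thickness_um: float = float("nan")
    rezi_percent: float = float("nan")
    ez_tv_percent: float = float("nan")
    n_valid_columns: int = 0
    axial_um_per_px: float = 3.5
    tv_alpha: float = 0.05
    beta: int = 3

    def as_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


def extract_layer_bands(mask: Union[ClassMap, np.ndarray]) -> LayerBands:
    """Column-wise upper (min row) and lower (max row) extent of each class."""
    lab = mask.labels if isinstance(mask, ClassMap) else np.asarray(mask)
    H, W = lab.shape
    upper, lower, present = {}, {}, {}
    rows = np.arange(H)[:, None]
    for c in range(1, 5):
        hit = lab == c
        pres = hit.any(axis=0)
        up = np.where(hit, rows, H).min(axis=0)
        lo = np.where(hit, rows, -1).max(axis=0)
        upper[c] = np.where(pres, up, 0).astype(int)
        lower[c] = np.where(pres, lo, 0).astype(int)
        present[c] = pres
    return LayerBands(upper=upper, lower=lower, present=present, n_columns=W)


def locate_peaks(image: Union[BScanImage, np.ndarray], bands: LayerBands) -> PeakTable:
    """Per-column intensity peaks inside each band's row range.

    The peak is the maximum intensity between the band's upper and lower rows;
    ties break to the smaller (inner) row.  The BM boundary is the outermost
    (largest) row of the IZ+RPE+BM band.  Columns missing any of OPL, ELM, EZ
    or the RPE complex are flagged invalid.
    """
    pix = image.pixels if isinstance(image, BScanImage) else np.asarray(image)
    H, W = pix.shape
    if W != bands.n_columns:
        raise ValueError("image width does not match the band table")
    rows = np.arange(H)[:, None]
    peak_row: Dict[str, np.ndarray] = {}
    peak_value: Dict[str, np.ndarray] = {}
    for name in _PEAK_CLASSES:
        up, lo, pres = bands.band(name)
        inside = (rows >= up[None, :]) & (rows <= lo[None, :]) & pres[None, :]
        masked = np.where(inside, pix, -np.inf)
        r = masked.argmax(axis=0)  # argmax takes the first (smallest row) on ties
        peak_row[name] = np.where(pres, r, 0).astype(int)
        peak_value[name] = np.where(pres, pix[r, np.arange(W)], np.nan)
    _, rpe_lo, rpe_pres = bands.band("rpe")
    valid = rpe_pres.copy()
    for name in _PEAK_CLASSES:
        valid &= bands.band(name)[2]
    return PeakTable(
        peak_row=peak_row,
        peak_value=peak_value,
        bm_row=np.where(rpe_pres, rpe_lo, 0).astype(int),
        valid=valid,
        n_columns=W,
    )


def _mean_sd(values: np.ndarray) -> Tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(np.mean(values)), sd


def weighted_peak_distances(
    peaks: PeakTable, axial_um_per_px: float = 3.5
) -> Dict[str, Tuple[float, float]]:
    """Mean ± SD (µm) of the four peak distances over valid columns.

    OPL_EZ = |row(EZ) − row(OPL)|·Sy, ELM_EZ = |row(ELM) − row(EZ)|·Sy,
    BM_EZ = |BM − row(EZ)|·Sy, ELM_BM = |row(ELM) − BM|·Sy.  Raises when no
    column is valid (the quantity is undefined, not zero).
    """
    v = peaks.valid
    if not v.any():
        raise ValueError("no valid columns: peak distances are undefined")
    sy = float(axial_um_per_px)
    ez = peaks.peak_row["ez"][v].astype(float)
    opl = peaks.peak_row["opl"][v].astype(float)
    elm = peaks.peak_row["elm"][v].astype(float)
    bm = peaks.bm_row[v].astype(float)
    return {
        "opl_ez": _mean_sd(np.abs(ez - opl) * sy),
        "elm_ez": _mean_sd(np.abs(elm - ez) * sy),
        "bm_ez": _mean_sd(np.abs(bm - ez) * sy),
        "elm_bm": _mean_sd(np.abs(elm - bm) * sy),
    }


def ez_thickness(bands: LayerBands, axial_um_per_px: float = 3.5) -> float:
    """Mean EZ band thickness in µm over EZ-bearing columns (inclusive pixel
    count, so a single-pixel band measures one axial pixel)."""
    up, lo, pres = bands.band("ez")
    if not pres.any():
        raise ValueError("no EZ anywhere: thickness is undefined")
    return float(np.mean((lo[pres] - up[pres] + 1.0)) * axial_um_per_px)


def rezi(peaks: PeakTable) -> float:
    """Relative EZ intensity: mean of (P(EZ) − P(OPL))/P(EZ) over valid
    columns with positive EZ peak, in percent.  Sign is preserved."""
    v = peaks.valid & (np.nan_to_num(peaks.peak_value["ez"], nan=0.0) > 0)
    if not v.any():
        raise ValueError("no valid columns with positive EZ peak: rEZI undefined")
    pez = peaks.peak_value["ez"][v]
    popl = peaks.peak_value["opl"][v]
    return float(np.mean((pez - popl) / pez) * 100.0)


def tv_denoise(
    image: Union[BScanImage, np.ndarray],
    alpha: float = 0.05,
    eps: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """ROF total-variation denoising: argmin_u ½‖u − f‖² + α·TV(u).

    Solved by Chambolle's dual projection scheme (stopping tolerance ``eps``
    on the relative cost decrease, capped at ``max_iter`` iterations); α = 0
    returns the input.  The result never has larger total variation than the
    input.
    """
    pix = image.pixels if isinstance(image, BScanImage) else np.asarray(image, dtype=np.float64)
    if not np.isfinite(pix).all():
        raise ValueError("non-finite intensities")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return pix.copy()
    return denoise_tv_chambolle(pix, weight=alpha, eps=eps, max_num_iter=max_iter)


def ez_granularity(
    image: Union[BScanImage, np.ndarray],
    bands: LayerBands,
    beta: int = 3,
    alpha: float = 0.05,
) -> Tuple[np.ndarray, float]:
    """EZ local variation per column and the EZ granularity scalar (percent).

    The image is TV-denoised first.  For each EZ-bearing column ``x`` with EZ
    rows ``Y``, ``EZ_LV(x) = Σ_{k=-β..β} Σ_{y∈Y} |P(x+k, y) − P(x, y)|`` with
    out-of-range neighbors skipped; ``EZ_TV = 100 · Σ_x EZ_LV(x) / (2 β N)``
    where ``N`` counts the columns in the sum.  Returns ``(ez_lv, ez_tv)``
    with ``ez_lv`` NaN in EZ-free columns.
    """
    if beta < 1 or beta % 2 == 0:
        raise ValueError("beta must be an odd positive neighborhood half-width")
    den = tv_denoise(image, alpha)
    up, lo, pres = bands.band("ez")
    if not pres.any():
        raise ValueError("no EZ anywhere: granularity is undefined")
    W = den.shape[1]
    ez_lv = np.full(W, np.nan)
    cols = np.flatnonzero(pres)
    for x in cols:
        base = den[up[x] : lo[x] + 1, x]
        acc = 0.0
        for k in range(-beta, beta + 1):
            xk = x + k
            if 0 <= xk < W:
                acc += float(np.abs(den[up[x] : lo[x] + 1, xk] - base).sum())
        ez_lv[x] = acc
    n = cols.size
    ez_tv = float(np.nansum(ez_lv) / (2.0 * beta * n) * 100.0)
    return ez_lv, ez_tv


def sample_at_eccentricity(
    values: np.ndarray,
    fovea_column: int,
    lateral_um_per_px: float,
    laterality: str = "right",
    offset_mm: float = 0.5,
    window_mm: float = 0.1,
) -> Dict[str, Tuple[float, float, int]]:
    """Mean ± SD of a per-column quantity at ±``offset_mm`` from the fovea.

    Returns ``{'nasal': (mean, sd, n), 'temporal': (mean, sd, n)}`` averaging
    over a ±``window_mm`` window around each locus; NaN entries (columns where
    the quantity is undefined) are ignored.  The nasal side points toward the
    optic disc: columns right of the fovea in left-eye scans and left of the
    fovea in right-eye scans.
    """
    values = np.asarray(values, dtype=np.float64)
    W = values.size
    off_px = offset_mm * 1000.0 / lateral_um_per_px
    win_px = max(int(round(window_mm * 1000.0 / lateral_um_per_px)), 0)
    if laterality == "left":
        side = {"nasal": +1, "temporal": -1}
    elif laterality == "right":
        side = {"nasal": -1, "temporal": +1}
    else:
        raise ValueError("laterality must be 'left' or 'right'")
    out: Dict[str, Tuple[float, float, int]] = {}
    for region, sgn in side.items():
        center = int(round(fovea_column + sgn * off_px))
        lo, hi = center - win_px, center + win_px
        if lo < 0 or hi >= W:
            raise ValueError(f"{region} sampling window [{lo}, {hi}] falls outside the scan")
        seg = values[lo : hi + 1]
        seg = seg[np.isfinite(seg)]
        mean, sd = _mean_sd(seg)
        out[region] = (mean, sd, int(seg.size))
    return out


def analyze_bscan(
    image: BScanImage,
    mask: Union[ClassMap, np.ndarray],
    alpha: float = 0.05,
    beta: int = 3,
    offset_mm: float = 0.5,
    window_mm: float = 0.1,
    regions: Tuple[str, ...] = ("full-scan", "nasal", "temporal"),
) -> Dict[str, BiomarkerRecord]:
    """Full biomarker panel for one segmented B-scan.

    The full-scan record averages over all valid columns; nasal/temporal
    records restrict every per-column quantity to a ±``window_mm`` window at
    ``offset_mm`` eccentricity before averaging.
    """
    bands = extract_layer_bands(mask)
    peaks = locate_peaks(image, bands)
    sy = image.axial_um_per_px
    ez_lv, _ = ez_granularity(image, bands, beta=beta, alpha=alpha)

    # per-column raw quantities (NaN where undefined)
    W = bands.n_columns
    ez_r = peaks.peak_row["ez"].astype(float)
    opl_r = peaks.peak_row["opl"].astype(float)
    elm_r = peaks.peak_row["elm"].astype(float)
    bm_r = peaks.bm_row.astype(float)
    v = peaks.valid
    nanv = np.where(v, 1.0, np.nan)
    per_col = {
        "opl_ez": np.abs(ez_r - opl_r) * sy * nanv,
        "elm_ez": np.abs(elm_r - ez_r) * sy * nanv,
        "bm_ez": np.abs(bm_r - ez_r) * sy * nanv,
        "elm_bm": np.abs(elm_r - bm_r) * sy * nanv,
    }
    up, lo, ez_pres = bands.band("ez")
    per_col["ez_th"] = np.where(ez_pres, (lo - up + 1.0) * sy, np.nan)
    pez = peaks.peak_value["ez"]
    rez_ok = v & (np.nan_to_num(pez, nan=0.0) > 0)
    per_col["rezi"] = np.where(rez_ok, (pez - peaks.peak_value["opl"]) / np.where(pez > 0, pez, 1.0) * 100.0, np.nan)
    per_col["ez_lv"] = ez_lv

    records: Dict[str, BiomarkerRecord] = {}
    for region in regions:
        if region == "full-scan":
            sel = {k: arr[np.isfinite(arr)] for k, arr in per_col.items()}
            stats = {k: _mean_sd(arr) for k, arr in sel.items()}
            n_valid = int(v.sum())
            n_lv = int(np.isfinite(ez_lv).sum())
            ez_tv = float(np.nansum(ez_lv) / (2.0 * beta * max(n_lv, 1)) * 100.0) if n_lv else float("nan")
        else:
            stats = {}
            n_valid = 0
            for k, arr in per_col.items():
                reg = sample_at_eccentricity(
                    arr, image.fovea_column, image.lateral_um_per_px,
                    image.laterality, offset_mm, window_mm,
                )[region]
                stats[k] = (reg[0], reg[1])
                if k == "opl_ez":
                    n_valid = reg[2]
            lv_reg = sample_at_eccentricity(
                ez_lv, image.fovea_column, image.lateral_um_per_px,
                image.laterality, offset_mm, window_mm,
            )[region]
            ez_tv = lv_reg[0] / (2.0 * beta) * 100.0 if lv_reg[2] else float("nan")
        records[region] = BiomarkerRecord(
            region=region,
            opl_ez_um=stats["opl_ez"][0], opl_ez_sd=stats["opl_ez"][1],
            elm_ez_um=stats["elm_ez"][0], elm_ez_sd=stats["elm_ez"][1],
            bm_ez_um=stats["bm_ez"][0], bm_ez_sd=stats["bm_ez"][1],
            elm_bm_um=stats["elm_bm"][0], elm_bm_sd=stats["elm_bm"][1],
            ez_thickness_um=stats["ez_th"][0],
            rezi_percent=stats["rezi"][0],
            ez_tv_percent=ez_tv,
            n_valid_columns=n_valid,
            axial_um_per_px=sy,
            tv_alpha=alpha,
            beta=beta,
        )
    return records
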