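"""Synthetic layered-retina phantoms.

Generates Spectralis-like SD-OCT B-scans (496-pixel axial depth, 768/1024-pixel
width, ~3.5 µm/pixel axial sampling) with four hyperreflective outer-retina
bands — OPL zone, ELM zone, EZ, and the IZ+RPE+BM complex — over a dark
background, a smooth foveal pit, multiplicative speckle noise, and two disease
knobs: lateral shortening of the surviving EZ (``ez_extent_mm``) and EZ
reflectance attenuation (``ez_attenuation``).

Every phantom carries an exact per-pixel ground-truth class map, so the
segmentation network, the biomarker extractors, and the en-face mapping can all
be validated against known geometry.

Class coding (shared with the whole package): 0 background, 1 EZ, 2 OPL zone,
3 ELM zone, 4 IZ+RPE+BM.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "LABELS",
    "PhantomSpec",
    "BScanImage",
    "ClassMap",
    "band_geometry",
    "generate_bscan",
    "generate_volume",
    "apply_speckle",
]

#: Fixed label semantics for the 5-class segmentation problem.
LABELS: Dict[str, int] = {"background": 0, "ez": 1, "opl": 2, "elm": 3, "rpe": 4}

#: Layer order from inner (vitreous side, low row index) to outer.
LAYER_ORDER: Tuple[str, ...] = ("opl", "elm", "ez", "rpe")


@dataclass
class BScanImage:
    """A single OCT B-scan: rows are axial depth (row 0 = vitreous side),
    columns are A-scan positions."""

    pixels: np.ndarray
    axial_um_per_px: float = 3.5
    lateral_um_per_px: float = 11.0
    fovea_column: int = 0
    laterality: str = "right"
    bscan_index: int = 0
    bscan_spacing_um: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        if not (0 <= self.fovea_column < self.pixels.shape[1]):
            raise ValueError("fovea_column outside image width")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class ClassMap:
    """Per-pixel labels in {0..4}, same raster geometry as its B-scan."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        bad = np.setdiff1d(np.unique(self.labels), np.arange(5))
        if bad.size:
            raise ValueError(f"labels outside 0..4: {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape


@dataclass
class PhantomSpec:
    """Geometry, reflectance and degradation parameters of a phantom B-scan.

    Band centers/thicknesses are in pixels (row units); default separations are
    chosen so that at 3.5 µm/pixel the noise-free biomarkers sit in the range
    reported for healthy outer retinas: OPL→EZ 129.5 µm, ELM→EZ 42 µm,
    EZ→BM 56 µm, ELM→BM 98 µm, EZ thickness 17.5 µm, rEZI 60%.
    """

    image_height: int = 496
    image_width: int = 768
    axial_um_per_px: float = 3.5
    lateral_um_per_px: float = 11.0

    # band center rows (inner→outer: OPL < ELM < EZ < RPE complex)
    center_rows: Dict[str, int] = field(
        default_factory=lambda: {"opl": 263, "elm": 288, "ez": 300, "rpe": 311}
    )
    thicknesses: Dict[str, int] = field(
        default_factory=lambda: {"opl": 9, "elm": 3, "ez": 5, "rpe": 11}
    )
    reflectances: Dict[str, float] = field(
        default_factory=lambda: {"opl": 0.34, "elm": 0.55, "ez": 0.85, "rpe": 0.80}
    )

    fovea_column: Optional[int] = None  # default: image center
    pit_depth: float = 30.0  # px, outward bow of the outer bands at the fovea
    pit_width: float = 60.0  # px, Gaussian sigma of the pit

    ez_extent_mm: Optional[float] = None  # half-width of surviving EZ; None = full scan
    ez_attenuation: float = 1.0  # multiplies EZ reflectance
    speckle_level: float = 0.2  # sd of unit-mean multiplicative speckle

    laterality: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fovea_column is None:
            self.fovea_column = self.image_width // 2

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not (0 <= self.fovea_column < self.image_width):
            raise ValueError("fovea_column outside image width")
        for name in LAYER_ORDER:
            if self.thicknesses[name] < 1:
                raise ValueError(f"thickness of {name!r} must be >= 1 px")
            if not (0.0 <= self.reflectances[name] <= 1.0):
                raise ValueError(f"reflectance of {name!r} must lie in [0, 1]")
        if not (0.0 <= self.ez_attenuation <= 1.0):
            raise ValueError("ez_attenuation must lie in [0, 1]")
        if self.speckle_level < 0:
            raise ValueError("speckle_level must be >= 0")
        if self.pit_depth < 0 or self.pit_width <= 0:
            raise ValueError("pit parameters must be non-negative (width positive)")
        # bands must be disjoint and ordered in every column, and inside the image
        geom = band_geometry(self)
        prev_ll = np.full(self.image_width, -1)
        for name in LAYER_ORDER:
            lu, ll, present = geom[name]
            if name != "ez" and not present.all():
                raise ValueError(f"layer {name!r} must span the full width")
            if (lu[present] <= prev_ll[present]).any():
                raise ValueError(f"band {name!r} overlaps the band above it")
            if (lu[present] < 0).any() or (ll[present] >= self.image_height).any():
                raise ValueError(f"band {name!r} exceeds the image height")
            prev_ll = np.where(present, ll, prev_ll)

    def replace(self, **kwargs) -> "PhantomSpec":
        return dataclasses.replace(self, **kwargs)


def compact_spec(
    image_height: int = 128, image_width: int = 128, pit_depth: float = 6.0, **overrides
) -> PhantomSpec:
    """A small phantom that keeps the default band thicknesses and axial
    separations (hence identical µm biomarkers) but crops the field of view.

    The outer-retina complex is positioned so the deepest band plus the foveal
    pit still fits; useful for fast training experiments and demos.
    """
    ez = image_height - 26 - int(np.ceil(pit_depth))
    if ez - 41 < 2:
        raise ValueError("image_height too small for the default band stack")
    centers = {"opl": ez - 37, "elm": ez - 12, "ez": ez, "rpe": ez + 11}
    spec = PhantomSpec(
        image_height=image_height,
        image_width=image_width,
        center_rows=centers,
        pit_depth=pit_depth,
        pit_width=max(image_width / 8.0, 4.0),
        **overrides,
    )
    spec.validate()
    return spec


def band_geometry(spec: PhantomSpec) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-column band boundaries implied by a spec.

    Returns, for each layer name, ``(upper_row, lower_row, present)`` arrays of
    length ``image_width``.  The foveal pit bows all outer bands outward by the
    same Gaussian-shaped shift, so inter-band separations are constant across
    columns.  The EZ band is present only within ``ez_extent_mm`` of the fovea.
    """
    x = np.arange(spec.image_width)
    shift = np.rint(
        spec.pit_depth * np.exp(-((x - spec.fovea_column) ** 2) / (2.0 * spec.pit_width**2))
    ).astype(int)

    if spec.ez_extent_mm is None:
        ez_present = np.ones(spec.image_width, dtype=bool)
    elif spec.ez_extent_mm <= 0:
        ez_present = np.zeros(spec.image_width, dtype=bool)
    else:
        dist_um = np.abs(x - spec.fovea_column) * spec.lateral_um_per_px
        ez_present = dist_um <= spec.ez_extent_mm * 1000.0

    geom = {}
    for name in LAYER_ORDER:
        t = spec.thicknesses[name]
        center = spec.center_rows[name] + shift
        lu = center - (t - 1) // 2
        ll = lu + t - 1
        present = ez_present if name == "ez" else np.ones(spec.image_width, dtype=bool)
        geom[name] = (lu, ll, present)
    return geom


def _paint_bands(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free image and label map from the spec geometry.

    Reflectance across each band follows a raised-cosine profile peaking at the
    band center, so per-A-scan intensity peaks are well defined and interior.
    """
    H, W = spec.image_height, spec.image_width
    img = np.zeros((H, W), dtype=np.float64)
    lab = np.zeros((H, W), dtype=np.uint8)
    geom = band_geometry(spec)
    rows = np.arange(H)[:, None]
    for name in LAYER_ORDER:
        lu, ll, present = geom[name]
        refl = spec.reflectances[name]
        if name == "ez":
            refl *= spec.ez_attenuation
        inside = (rows >= lu[None, :]) & (rows <= ll[None, :]) & present[None, :]
        center = (lu + ll) / 2.0
        half = (ll - lu) / 2.0
        profile = refl * np.cos(0.5 * np.pi * (rows - center[None, :]) / (half[None, :] + 1.0))
        img[inside] = profile[inside]
        lab[inside] = LABELS[name]
    return img, lab


def generate_bscan(
    spec: PhantomSpec, seed: Optional[int] = None
) -> Tuple[BScanImage, ClassMap]:
    """Generate one phantom B-scan and its exact ground-truth class map.

    Identical ``(spec, seed)`` pairs yield bit-identical output.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    img, lab = _paint_bands(spec)
    bscan = BScanImage(
        pixels=img,
        axial_um_per_px=spec.axial_um_per_px,
        lateral_um_per_px=spec.lateral_um_per_px,
        fovea_column=spec.fovea_column,
        laterality=spec.laterality,
    )
    if spec.speckle_level > 0:
        bscan = apply_speckle(bscan, spec.speckle_level, seed)
    return bscan, ClassMap(labels=lab)


def generate_volume(
    spec: PhantomSpec,
    n_bscans: int,
    footprint_mm: Tuple[float, float],
    seed: Optional[int] = None,
    volume_extent_mm: float = 6.0,
) -> Tuple[List[BScanImage], List[ClassMap]]:
    """Generate a volume scan whose EZ footprint is an ellipse.

    ``footprint_mm`` gives the ellipse semi-axes ``(a, b)``: ``a`` along the
    B-scan (lateral) direction and ``b`` across B-scans.  B-scans are spaced
    evenly over ``volume_extent_mm`` centered on the fovea; each B-scan's EZ
    half-width is the elliptical cross-section at its position.
    """
    if n_bscans < 2:
        raise ValueError("a volume needs at least 2 B-scans")
    a, b = footprint_mm
    if a < 0 or b < 0:
        raise ValueError("footprint semi-axes must be non-negative")
    if seed is None:
        seed = spec.seed
    positions_mm = np.linspace(-volume_extent_mm / 2.0, volume_extent_mm / 2.0, n_bscans)
    spacing_um = (positions_mm[1] - positions_mm[0]) * 1000.0
    images: List[BScanImage] = []
    masks: List[ClassMap] = []
    for j, y in enumerate(positions_mm):
        if a > 0 and b > 0 and abs(y) < b:
            half_w = a * float(np.sqrt(1.0 - (y / b) ** 2))
        else:
            half_w = 0.0
        sj = spec.replace(ez_extent_mm=half_w)
        img, mask = generate_bscan(sj, seed=(seed + j) % (2**31))
        img.bscan_index = j
        img.bscan_spacing_um = float(spacing_um)
        images.append(img)
        masks.append(mask)
    return images, masks


def apply_speckle(image: BScanImage, level: float, seed: int) -> BScanImage:
    """Multiplicative unit-mean gamma speckle (sd = ``level``), clipped to [0, 1].

    ``level`` 0 returns the input unchanged.
    """
    if level < 0:
        raise ValueError("speckle level must be >= 0")
    if level == 0:
        return image
    rng = np.random.default_rng(seed)
    k = 1.0 / level**2  # shape k, scale 1/k -> mean 1, variance level^2
    noise = rng.gamma(shape=k, scale=1.0 / k, size=image.pixels.shape)
    noisy = np.clip(image.pixels * noise, 0.0, 1.0)
    return dataclasses.replace(image, pixels=noisy)
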