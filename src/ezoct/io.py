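"""Raster and metadata I/O plus run configuration.

B-scans travel as 8- or 16-bit grayscale TIFF/PNG with a JSON metadata sidecar
(``<image>.json``) carrying axial/lateral scales, fovea column, laterality and
B-scan spacing; label maps as 8-bit rasters with values in {0..4}.  Intensities
are rescaled to [0, 1] from the source bit depth on read.  Missing sidecars
fall back to Spectralis-like defaults (3.5 µm axial, 11.0 µm lateral) with a
logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional, Union

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .phantom import BScanImage, ClassMap

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_metadata",
    "write_metadata",
    "RunConfig",
]

logger = logging.getLogger("ezoct")

_DEFAULT_META = {
    "axial_um_per_px": 3.5,
    "lateral_um_per_px": 11.0,
    "fovea_column": None,
    "laterality": "right",
    "bscan_index": 0,
    "bscan_spacing_um": 0.0,
}


def _sidecar(path: Union[str, Path]) -> Path:
    return Path(str(path) + ".json")


def write_metadata(path: Union[str, Path], image: BScanImage) -> Path:
    meta = {
        "axial_um_per_px": image.axial_um_per_px,
        "lateral_um_per_px": image.lateral_um_per_px,
        "fovea_column": image.fovea_column,
        "laterality": image.laterality,
        "bscan_index": image.bscan_index,
        "bscan_spacing_um": image.bscan_spacing_um,
    }
    out = _sidecar(path)
    out.write_text(json.dumps(meta, indent=1))
    return out


def read_metadata(path: Union[str, Path]) -> Dict[str, Any]:
    side = _sidecar(path)
    meta = dict(_DEFAULT_META)
    if side.exists():
        meta.update(json.loads(side.read_text()))
    else:
        logger.warning(
            "no metadata sidecar for %s; applying defaults (axial 3.5 um/px, lateral 11.0 um/px)",
            path,
        )
    return meta


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def read_image(path: Union[str, Path]) -> BScanImage:
    """Read a grayscale B-scan raster plus its sidecar into a BScanImage."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not single-channel grayscale (shape {arr.shape})")
    if arr.dtype == np.uint8:
        pix = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        pix = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        pix = np.clip(arr.astype(np.float64), 0.0, 1.0)
    else:
        raise ValueError(f"unsupported raster dtype {arr.dtype}")
    meta = read_metadata(path)
    if meta["fovea_column"] is None:
        meta["fovea_column"] = pix.shape[1] // 2
    return BScanImage(
        pixels=pix,
        axial_um_per_px=meta["axial_um_per_px"],
        lateral_um_per_px=meta["lateral_um_per_px"],
        fovea_column=int(meta["fovea_column"]),
        laterality=meta["laterality"],
        bscan_index=int(meta.get("bscan_index", 0)),
        bscan_spacing_um=float(meta.get("bscan_spacing_um", 0.0)),
    )


def write_image(path: Union[str, Path], image: BScanImage, bit_depth: int = 16) -> Path:
    """Write a B-scan as 8- or 16-bit grayscale TIFF/PNG plus JSON sidecar."""
    path = Path(path)
    if bit_depth == 16:
        arr = np.rint(image.pixels * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.rint(image.pixels * 255.0).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    write_metadata(path, image)
    return path


def read_mask(path: Union[str, Path]) -> ClassMap:
    """Read a label raster; values outside {0..4} are an error naming them."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel label raster")
    return ClassMap(labels=arr)  # ClassMap validates the value set


def write_mask(path: Union[str, Path], mask: ClassMap) -> Path:
    path = Path(path)
    arr = mask.labels.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    return path


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see ``ezoct.pipeline.run_pipeline``).

    Every stochastic stage carries an explicit seed so reruns with an identical
    config reproduce all deterministic outputs.
    """

    out_dir: str = "ezoct_run"
    seed: int = 0
    # phantom study conditions
    n_controls: int = 6
    n_patients: int = 6
    image_height: int = 128
    image_width: int = 128
    n_volume_bscans: int = 25
    footprint_mm: tuple = (2.0, 2.5)
    # segmentation
    epochs: int = 4
    batch_size: int = 4
    learning_rate: float = 1e-3
    loss_lambda: float = 0.5
    # biomarker parameters
    tv_alpha: float = 0.05
    beta: int = 3
    offset_mm: float = 0.25
    window_mm: float = 0.05
    # en-face
    roi_shape: str = "square"
    roi_diameter_mm: float = 6.0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "footprint_mm" in data:
            data["footprint_mm"] = tuple(data["footprint_mm"])
        return cls(**data)

    def to_dict(self) -> Dict[str, Any]:
        d = asdict(self)
        d["footprint_mm"] = list(self.footprint_mm)
        return d
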