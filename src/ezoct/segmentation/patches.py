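"""B-scan patching and probability stitching.

B-scans are wider than the network's input, so they are tiled into
``patch_height x patch_width`` patches with a fixed overlap (defaults
496 x 128, overlap 64, i.e. column stride 64).  Scans shorter than the patch
height are reflect-padded at the bottom; scans taller than it are tiled
vertically with the same overlap.  When an axis is not an exact multiple of
the stride the source is reflect-padded at the trailing edge so the final
patch still has full size; the stitcher crops the padding back off.
Overlapping predictions are averaged (arithmetic mean of probabilities, then
renormalized), which is order-independent and idempotent when patches agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np

from ..phantom import BScanImage

__all__ = ["PatchSet", "partition_bscan", "stitch_probabilities"]


@dataclass
class PatchSet:
    """Ordered patches plus the bookkeeping needed to invert the tiling."""

    patches: List[np.ndarray]
    origins: List[Tuple[int, int]]  # (row, column) of each patch's top-left
    source_height: int
    source_width: int
    patch_height: int
    patch_width: int
    overlap: int

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def origin_columns(self) -> List[int]:
        return [c for _, c in self.origins]

    @property
    def stride(self) -> int:
        return self.patch_width - self.overlap


def _as_array(image: Union[BScanImage, np.ndarray]) -> np.ndarray:
    return image.pixels if isinstance(image, BScanImage) else np.asarray(image)


def _tile_starts(size: int, patch: int, stride: int) -> List[int]:
    n = int(np.ceil((size - patch) / stride)) + 1 if size > patch else 1
    return [i * stride for i in range(n)]


def partition_bscan(
    image: Union[BScanImage, np.ndarray],
    patch_height: int = 496,
    patch_width: int = 128,
    overlap: int = 64,
) -> PatchSet:
    """Tile a B-scan into overlapping patches covering every pixel.

    The number of column tiles for width ``W`` is
    ``ceil((W - patch_width) / stride) + 1`` (e.g. 11 for 768-wide and 15 for
    1024-wide scans at the default stride 64).  Raises if the image is narrower
    than the patch width.
    """
    pix = _as_array(image)
    H, W = pix.shape
    if overlap >= patch_width or overlap < 0:
        raise ValueError("overlap must satisfy 0 <= overlap < patch_width")
    if W < patch_width:
        raise ValueError(f"image width {W} is narrower than the patch width {patch_width}")
    if H < patch_height:  # pad at the bottom (choroid side) by reflection
        pix = np.pad(pix, ((0, patch_height - H), (0, 0)), mode="reflect")
    stride_w = patch_width - overlap
    stride_h = max(patch_height - overlap, 1)
    row_starts = _tile_starts(pix.shape[0], patch_height, stride_h)
    col_starts = _tile_starts(W, patch_width, stride_w)
    bottom = row_starts[-1] + patch_height
    right = col_starts[-1] + patch_width
    pad_h, pad_w = bottom - pix.shape[0], right - W
    if pad_h > 0 or pad_w > 0:
        pix = np.pad(pix, ((0, max(pad_h, 0)), (0, max(pad_w, 0))), mode="reflect")
    origins = [(r, c) for r in row_starts for c in col_starts]
    patches = [pix[r : r + patch_height, c : c + patch_width].copy() for r, c in origins]
    return PatchSet(
        patches=patches,
        origins=origins,
        source_height=H,
        source_width=W,
        patch_height=patch_height,
        patch_width=patch_width,
        overlap=overlap,
    )


def stitch_probabilities(
    patch_probs: Sequence[np.ndarray], patchset: PatchSet
) -> np.ndarray:
    """Reassemble per-patch class probabilities into a full-scan map.

    ``patch_probs`` holds one ``(C, patch_height, patch_width)`` block per
    patch.  Overlapping pixels are averaged and renormalized; the result is
    ``(C, source_height, source_width)`` with per-pixel probabilities summing
    to 1.
    """
    if len(patch_probs) != len(patchset):
        raise ValueError("one probability block per patch is required")
    C = None
    for block in patch_probs:
        block = np.asarray(block)
        if block.ndim != 3 or block.shape[1:] != (patchset.patch_height, patchset.patch_width):
            raise ValueError("probability block shape does not match the patch set")
        if C is None:
            C = block.shape[0]
        elif block.shape[0] != C:
            raise ValueError("inconsistent class counts across blocks")
    bottom = max(r for r, _ in patchset.origins) + patchset.patch_height
    right = max(c for _, c in patchset.origins) + patchset.patch_width
    acc = np.zeros((C, bottom, right), dtype=np.float64)
    cnt = np.zeros((bottom, right), dtype=np.float64)
    for block, (r0, c0) in zip(patch_probs, patchset.origins):
        acc[:, r0 : r0 + patchset.patch_height, c0 : c0 + patchset.patch_width] += block
        cnt[r0 : r0 + patchset.patch_height, c0 : c0 + patchset.patch_width] += 1.0
    acc /= cnt[None, :, :]
    acc = acc[:, : patchset.source_height, : patchset.source_width]
    total = acc.sum(axis=0, keepdims=True)
    return acc / np.where(total > 0, total, 1.0)
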