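"""Participant rosters, leakage-free dataset splitting, and augmentation.

Splitting is by participant (all of a participant's eyes/scans travel
together) and stratified by cohort, so a network never sees validation
participants during training.  Per-cohort training counts use
round-half-away-from-zero, which reproduces 75/18 train vs 19/4 validation
for a 94-control / 22-patient roster at an 80/20 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from ..phantom import BScanImage

__all__ = ["Roster", "split_by_participant", "augment", "AugmentConfig"]


@dataclass
class Roster:
    """Participants with cohort labels and attached scan identifiers."""

    participants: List[str] = field(default_factory=list)
    cohorts: Dict[str, str] = field(default_factory=dict)  # id -> "control" | "patient"
    scans: Dict[str, List[str]] = field(default_factory=dict)  # id -> scan paths/ids

    def add(self, participant_id: str, cohort: str, scans: Optional[Sequence[str]] = None) -> None:
        if cohort not in ("control", "patient"):
            raise ValueError("cohort must be 'control' or 'patient'")
        if participant_id in self.cohorts:
            raise ValueError(f"duplicate participant {participant_id!r}")
        self.participants.append(participant_id)
        self.cohorts[participant_id] = cohort
        self.scans[participant_id] = list(scans or [])

    def subset(self, ids: Sequence[str]) -> "Roster":
        sub = Roster()
        for pid in ids:
            sub.add(pid, self.cohorts[pid], self.scans[pid])
        return sub

    def count(self, cohort: str) -> int:
        return sum(1 for p in self.participants if self.cohorts[p] == cohort)

    def __len__(self) -> int:
        return len(self.participants)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_by_participant(
    roster: Roster, train_fraction: float = 0.8, seed: int = 0
) -> Tuple[Roster, Roster]:
    """Stratified participant-level split into (train, validation) rosters.

    Per-cohort train counts are ``round(cohort_size * train_fraction)``
    (half away from zero) and do not depend on the seed; only the membership
    is randomized.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if len(roster) == 0:
        raise ValueError("empty roster")
    rng = np.random.default_rng(seed)
    train_ids: List[str] = []
    val_ids: List[str] = []
    for cohort in ("control", "patient"):
        ids = [p for p in roster.participants if roster.cohorts[p] == cohort]
        if not ids:
            continue
        order = rng.permutation(len(ids))
        n_train = _round_half_away(len(ids) * train_fraction)
        shuffled = [ids[i] for i in order]
        train_ids.extend(shuffled[:n_train])
        val_ids.extend(shuffled[n_train:])
    return roster.subset(train_ids), roster.subset(val_ids)


@dataclass
class AugmentConfig:
    """Magnitudes for the geometric and intensity transforms."""

    flip_prob: float = 0.5
    max_shift_px: int = 8  # both axes
    scale_range: Tuple[float, float] = (0.95, 1.05)
    gamma_range: Tuple[float, float] = (0.7, 1.4)
    brightness: float = 0.1
    contrast_range: Tuple[float, float] = (0.8, 1.2)
    noise_sigma: float = 0.02


def _geom_image(img: np.ndarray, shift: Tuple[int, int], scale: float, order: int) -> np.ndarray:
    out = ndimage.shift(img, shift, order=order, mode="nearest")
    if scale != 1.0:
        H, W = out.shape
        zoomed = ndimage.zoom(out, scale, order=order, mode="nearest")
        zh, zw = zoomed.shape
        if scale >= 1.0:  # center crop
            r0, c0 = (zh - H) // 2, (zw - W) // 2
            out = zoomed[r0 : r0 + H, c0 : c0 + W]
        else:  # center pad
            out = np.zeros_like(img)
            r0, c0 = (H - zh) // 2, (W - zw) // 2
            out[r0 : r0 + zh, c0 : c0 + zw] = zoomed
    return out


def augment(
    image: Union[BScanImage, np.ndarray],
    mask: np.ndarray,
    seed: int,
    config: Optional[AugmentConfig] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded augmentation of a (B-scan, label map) pair.

    Geometric transforms (horizontal flip, small integer shift, small
    isotropic scale) are applied identically to image and mask, with
    nearest-neighbor resampling for labels.  Intensity transforms (gamma,
    brightness/contrast jitter, additive Gaussian noise) touch the image only.
    """
    cfg = config or AugmentConfig()
    img = (image.pixels if isinstance(image, BScanImage) else np.asarray(image)).astype(np.float64)
    lab = np.asarray(mask)
    if img.shape != lab.shape:
        raise ValueError("image and mask shapes must match")
    rng = np.random.default_rng(seed)

    if rng.random() < cfg.flip_prob:
        img = img[:, ::-1].copy()
        lab = lab[:, ::-1].copy()
    shift = tuple(int(s) for s in rng.integers(-cfg.max_shift_px, cfg.max_shift_px + 1, size=2))
    scale = float(rng.uniform(*cfg.scale_range))
    if shift != (0, 0) or scale != 1.0:
        img = _geom_image(img, shift, scale, order=1)
        lab = _geom_image(lab.astype(np.float64), shift, scale, order=0).astype(lab.dtype)

    gamma = float(rng.uniform(*cfg.gamma_range))
    gain = float(rng.uniform(*cfg.contrast_range))
    offset = float(rng.uniform(-cfg.brightness, cfg.brightness))
    img = np.clip(gain * np.power(np.clip(img, 0, 1), gamma) + offset, 0.0, 1.0)
    if cfg.noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, cfg.noise_sigma, img.shape), 0.0, 1.0)
    return img, lab
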