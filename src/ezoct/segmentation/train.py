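"""Training, inference, and segmentation quality metrics.

``train_segmenter`` minimizes the combined Dice / weighted-cross-entropy loss
with Adam over shuffled mini-batches of patches; ``predict_classmap`` runs the
partition -> forward -> stitch -> argmax chain on a full B-scan (argmax ties
break toward the lower class index); ``segmentation_metrics`` reports
per-class Dice and sensitivity, leaving classes absent from both masks
undefined (NaN) rather than scoring them 1.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ..phantom import BScanImage, ClassMap, LABELS
from . import _nn
from .data import AugmentConfig, augment
from .model import UNet, UNetConfig, build_unet, loss_and_logit_grad, softmax_channels
from .patches import partition_bscan, stitch_probabilities

__all__ = [
    "inverse_frequency_weights",
    "train_segmenter",
    "predict_classmap",
    "segmentation_metrics",
]

Pair = Tuple[np.ndarray, np.ndarray]


def _as_pair(pair) -> Pair:
    img, mask = pair
    img = img.pixels if isinstance(img, BScanImage) else np.asarray(img)
    mask = mask.labels if isinstance(mask, ClassMap) else np.asarray(mask)
    if img.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    return img.astype(np.float64), mask.astype(np.int64)


def inverse_frequency_weights(masks: Sequence[np.ndarray], n_classes: int = 5) -> np.ndarray:
    """Inverse-class-frequency weights over a mask collection, normalized to
    mean 1.  Classes never seen get the largest observed weight."""
    counts = np.zeros(n_classes, dtype=np.float64)
    for m in masks:
        counts += np.bincount(np.asarray(m).ravel(), minlength=n_classes)[:n_classes]
    total = counts.sum()
    with np.errstate(divide="ignore"):
        w = np.where(counts > 0, total / np.maximum(counts, 1.0), 0.0)
    if (w == 0).any():
        w[w == 0] = w[w > 0].max() if (w > 0).any() else 1.0
    return w / w.mean()


def _extract_patches(pairs: Sequence[Pair], cfg: UNetConfig) -> List[Pair]:
    """Cut every (image, mask) pair into aligned network-sized patches."""
    out: List[Pair] = []
    for img, mask in pairs:
        ps_img = partition_bscan(img, cfg.patch_height, cfg.patch_width, cfg.patch_overlap)
        ps_mask = partition_bscan(mask.astype(np.float64), cfg.patch_height, cfg.patch_width, cfg.patch_overlap)
        for pi, pm in zip(ps_img.patches, ps_mask.patches):
            out.append((pi, pm.astype(np.int64)))
    return out


def train_segmenter(
    train_pairs: Sequence,
    val_pairs: Sequence,
    config: UNetConfig,
    seed: int = 0,
    augment_config: Optional[AugmentConfig] = None,
    verbose: bool = False,
) -> Tuple[UNet, Dict[str, list]]:
    """Train the U-Net on (image, mask) pairs; returns (model, history).

    Inputs may be full B-scans (they are patched to the configured size) or
    already patch-sized arrays.  History carries per-epoch mean training loss
    and, when a validation set is given, per-epoch EZ-class Dice.
    """
    config.validate()
    pairs = [_as_pair(p) for p in train_pairs]
    if not pairs:
        raise ValueError("empty training set")
    vpairs = [_as_pair(p) for p in val_pairs] if val_pairs else []
    patches = _extract_patches(pairs, config)

    if config.class_weights is None:
        weights = inverse_frequency_weights([m for _, m in patches], config.n_classes)
    else:
        weights = np.asarray(config.class_weights, dtype=np.float64)

    model = build_unet(config)
    model._class_weights = weights
    opt = _nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(seed)
    history: Dict[str, list] = {"loss": [], "val_dice_ez": []}

    n = len(patches)
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            batch = [patches[i] for i in order[start : start + bs]]
            if config.augment:
                seeds = rng.integers(0, 2**31, size=len(batch))
                batch = [augment(im, mk, int(s), augment_config) for (im, mk), s in zip(batch, seeds)]
            x = np.stack([im for im, _ in batch])
            y = np.stack([mk for _, mk in batch])
            logits = model.forward(x, training=True)
            loss, dlogits = loss_and_logit_grad(logits, y, config.loss_lambda, weights)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            model.backward(dlogits.astype(model.dtype))
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        if vpairs:
            dices = []
            for img, mask in vpairs:
                pred, _ = predict_classmap(model, img)
                m = segmentation_metrics(pred, ClassMap(labels=mask.astype(np.uint8)))
                d = m["dice"][LABELS["ez"]]
                if np.isfinite(d):
                    dices.append(d)
            history["val_dice_ez"].append(float(np.mean(dices)) if dices else float("nan"))
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs}  loss {history['loss'][-1]:.4f}"
            if vpairs:
                msg += f"  val EZ dice {history['val_dice_ez'][-1]:.4f}"
            print(msg)
    model._trained = True
    return model, history


def predict_classmap(
    model: UNet, image: Union[BScanImage, np.ndarray]
) -> Tuple[ClassMap, np.ndarray]:
    """Segment a full B-scan: patch, forward in eval mode, stitch, argmax.

    Returns the label map and the stitched per-pixel probabilities
    ``(5, H, W)``.  ``np.argmax`` breaks probability ties toward the lower
    class index.
    """
    if not isinstance(model, UNet):
        raise TypeError("model must be a UNet")
    cfg = model.config
    ps = partition_bscan(image, cfg.patch_height, cfg.patch_width, cfg.patch_overlap)
    blocks = []
    for patch in ps.patches:
        probs = model.predict_proba(patch[None])[0]  # (H, W, 5)
        blocks.append(probs.transpose(2, 0, 1))
    stitched = stitch_probabilities(blocks, ps)
    labels = np.argmax(stitched, axis=0).astype(np.uint8)
    return ClassMap(labels=labels), stitched


def segmentation_metrics(pred: ClassMap, truth: ClassMap, n_classes: int = 5) -> Dict[str, np.ndarray]:
    """Per-class Dice 2|A∩B|/(|A|+|B|) and sensitivity |A∩B|/|B| (B = truth).

    Classes absent from both masks are NaN (undefined), not 1.
    """
    a = pred.labels if isinstance(pred, ClassMap) else np.asarray(pred)
    b = truth.labels if isinstance(truth, ClassMap) else np.asarray(truth)
    if a.shape != b.shape:
        raise ValueError("prediction and truth shapes must match")
    for arr in (a, b):
        bad = np.setdiff1d(np.unique(arr), np.arange(n_classes))
        if bad.size:
            raise ValueError(f"labels outside 0..{n_classes - 1}: {bad.tolist()}")
    dice = np.full(n_classes, np.nan)
    sens = np.full(n_classes, np.nan)
    for c in range(n_classes):
        in_a = a == c
        in_b = b == c
        na, nb = in_a.sum(), in_b.sum()
        inter = (in_a & in_b).sum()
        if na + nb > 0:
            dice[c] = 2.0 * inter / (na + nb)
        if nb > 0:
            sens[c] = inter / nb
    return {"dice": dice, "sensitivity": sens}
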