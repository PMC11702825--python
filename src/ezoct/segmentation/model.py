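"""Four-level U-Net for 5-class outer-retina segmentation, plus the combined
Dice / weighted-cross-entropy training loss.

The architecture: four double-convolution encoder blocks (16, 32, 64, 128
filters, 5x5 kernels, batch normalization, leaky rectifier), 2x2 max-pool
downsampling between them, a mirrored decoder using 2x2 transposed-convolution
upsampling with skip connections, and a final 1x1 convolution onto five class
channels followed by a softmax.  With the default configuration the network has
about 1.26 million parameters.

The loss combines a soft multi-class Dice loss and a class-weighted
cross-entropy:

    L(y, p) = (1 - lambda) * L_Dice(y, p) + lambda * L_wCE(y, p)

with lambda in [0, 1] and Dice smoothing epsilon = 1 in both numerator and
denominator, so classes absent from a batch contribute a loss of ~0 rather
than 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _nn

__all__ = ["UNetConfig", "UNet", "build_unet", "combined_loss", "softmax_channels"]

DICE_EPS = 1.0


@dataclass
class UNetConfig:
    """Architecture and training hyperparameters.

    ``loss_lambda`` weights cross-entropy against Dice; ``class_weights`` of
    ``None`` means inverse-class-frequency weights computed on the training set
    (normalized to mean 1), the standard remedy for the thin EZ/ELM bands.
    """

    levels: int = 4
    base_filters: int = 16
    kernel_size: int = 5
    n_classes: int = 5
    leaky_slope: float = 0.1
    loss_lambda: float = 0.5
    class_weights: Optional[Sequence[float]] = None
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 8
    patch_height: int = 496
    patch_width: int = 128
    patch_overlap: int = 64
    augment: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 levels")
        if self.base_filters < 1:
            raise ValueError("base_filters must be positive")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if self.n_classes != 5:
            raise ValueError("this segmentation problem has exactly 5 classes")
        if not (0.0 <= self.loss_lambda <= 1.0):
            raise ValueError("loss_lambda must lie in [0, 1]")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if w.shape != (self.n_classes,) or (w < 0).any():
                raise ValueError("class_weights must be 5 non-negative numbers")
        if self.patch_overlap >= self.patch_width:
            raise ValueError("overlap must be smaller than the patch width")
        mult = 2 ** (self.levels - 1)
        if self.patch_height % mult or self.patch_width % mult:
            raise ValueError(f"patch size must be divisible by {mult}")


class _ConvBlock:
    """(conv -> batch norm -> leaky ReLU) x 2."""

    def __init__(self, in_ch, out_ch, k, slope, rng, dtype):
        self.layers = [
            _nn.Conv2d(in_ch, out_ch, k, rng, dtype),
            _nn.BatchNorm2d(out_ch, dtype=dtype),
            _nn.LeakyReLU(slope),
            _nn.Conv2d(out_ch, out_ch, k, rng, dtype),
            _nn.BatchNorm2d(out_ch, dtype=dtype),
            _nn.LeakyReLU(slope),
        ]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class UNet:
    """Maps a batch of single-channel patches (N, H, W) to per-pixel class
    logits/probabilities (N, H, W, 5).  H and W must be divisible by
    2**(levels-1)."""

    def __init__(self, config: UNetConfig, dtype=np.float32):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        L, f0, k, s = config.levels, config.base_filters, config.kernel_size, config.leaky_slope
        filters = [f0 * 2**i for i in range(L)]  # e.g. 16, 32, 64, 128
        self.enc = []
        in_ch = 1
        for f in filters:
            self.enc.append(_ConvBlock(in_ch, f, k, s, rng, dtype))
            in_ch = f
        self.pools = [_nn.MaxPool2d() for _ in range(L - 1)]
        self.ups = []
        self.dec = []
        for i in range(L - 2, -1, -1):
            self.ups.append(_nn.ConvTranspose2d(filters[i + 1], filters[i], rng, dtype))
            self.dec.append(_ConvBlock(2 * filters[i], filters[i], k, s, rng, dtype))
        self.head = _nn.Conv2d(filters[0], config.n_classes, 1, rng, dtype)
        self.dtype = dtype
        self._trained = False

    # -- plumbing ----------------------------------------------------------
    def parameters(self):
        params = []
        for block in self.enc + self.dec:
            params.extend(block.parameters())
        for up in self.ups:
            params.extend(up.parameters())
        params.extend(self.head.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits (N, H, W, n_classes) from patches (N, H, W[, 1])."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[..., None]
        mult = 2 ** (self.config.levels - 1)
        if x.shape[1] % mult or x.shape[2] % mult:
            raise ValueError(f"input spatial dims must be divisible by {mult}")
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x, training)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, training)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training)
            x = np.concatenate([skip, x], axis=-1)
            x = dec.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        grad = self.head.backward(dlogits)
        skip_grads = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            grad = dec.backward(grad)
            skip_ch = grad.shape[-1] // 2
            skip_grads.append(grad[..., :skip_ch])
            grad = up.backward(grad[..., skip_ch:])
        # decoder ran bottom-up in reverse, so skip_grads[i] pairs with enc[i]
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                grad = self.pools[i].backward(grad)
                grad = grad + skip_grads[i]
            grad = self.enc[i].backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (N, H, W, 5) in eval mode."""
        return softmax_channels(self.forward(x, training=False))

    # -- persistence ---------------------------------------------------------
    def _all_layers(self):
        layers = []
        for block in self.enc:
            layers.extend(block.layers)
        for up in self.ups:
            layers.append(up)
        for block in self.dec:
            layers.extend(block.layers)
        layers.append(self.head)
        return layers

    _STATE_ATTRS = ("W", "b", "gamma", "beta", "running_mean", "running_var")

    def save(self, path) -> None:
        """Checkpoint as an .npz of arrays (with an embedded config header)
        plus a human-readable architecture JSON sidecar."""
        import dataclasses as _dc
        import json as _json
        from pathlib import Path as _Path

        cfg_json = _json.dumps(_dc.asdict(self.config), indent=1)
        arrays = {"__config__": np.frombuffer(cfg_json.encode(), dtype=np.uint8)}
        for i, layer in enumerate(self._all_layers()):
            for attr in self._STATE_ATTRS:
                if hasattr(layer, attr):
                    arrays[f"{i}.{attr}"] = getattr(layer, attr)
        np.savez(path, **arrays)
        _Path(str(path) + ".arch.json").write_text(cfg_json)

    @classmethod
    def load(cls, path) -> "UNet":
        import json as _json

        with np.load(path) as data:
            cfg = UNetConfig(**_json.loads(bytes(data["__config__"]).decode()))
            if cfg.class_weights is not None:
                cfg.class_weights = list(cfg.class_weights)
            model = cls(cfg)
            for i, layer in enumerate(model._all_layers()):
                for attr in cls._STATE_ATTRS:
                    key = f"{i}.{attr}"
                    if key in data:
                        getattr(layer, attr)[...] = data[key]
        model._trained = True
        return model


def build_unet(config: UNetConfig, dtype=np.float32) -> UNet:
    """Construct the network from a validated configuration."""
    return UNet(config, dtype=dtype)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over the trailing (class) axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return e / e.sum(axis=-1, keepdims=True)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float64)[labels]


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    return np.clip(p, 0.0, 1.0)


def combined_loss(
    y: np.ndarray,
    p_hat: np.ndarray,
    loss_lambda: float = 0.5,
    class_weights: Optional[Sequence[float]] = None,
) -> float:
    """Combined loss (1-lambda)*Dice + lambda*weighted-CE on probabilities.

    ``y`` is either an integer label map (N, H, W) or one-hot (N, H, W, C);
    ``p_hat`` is (N, H, W, C) probabilities.  The Dice term averages the smoothed
    per-class soft Dice over all classes; the CE term is the weighted mean of
    per-pixel negative log-likelihoods (weights normalized by their total mass).
    """
    p = _check_probs(p_hat)
    C = p.shape[-1]
    if y.ndim == p.ndim - 1:
        y = _one_hot(np.asarray(y), C)
    y = np.asarray(y, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("shape mismatch between ground truth and probabilities")
    if class_weights is None:
        w = np.ones(C)
    else:
        w = np.asarray(class_weights, dtype=np.float64)
    axes = tuple(range(p.ndim - 1))
    inter = (p * y).sum(axis=axes)
    dice = (2.0 * inter + DICE_EPS) / (p.sum(axis=axes) + y.sum(axis=axes) + DICE_EPS)
    dice_loss = 1.0 - dice.mean()
    pix_w = y @ w  # (N, H, W)
    ce = -(pix_w * (y * np.log(np.clip(p, 1e-12, 1.0))).sum(axis=-1)).sum() / pix_w.sum()
    lam = float(loss_lambda)
    return float((1.0 - lam) * dice_loss + lam * ce)


def loss_and_logit_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    loss_lambda: float,
    class_weights: np.ndarray,
) -> Tuple[float, np.ndarray]:
    """Loss value and its analytic gradient with respect to the logits.

    Fuses softmax with the combined loss so training avoids the (numerically
    awkward) Jacobian of softmax applied to a clipped probability tensor.
    """
    p = softmax_channels(logits)
    C = p.shape[-1]
    y = _one_hot(np.asarray(labels), C)
    w = np.asarray(class_weights, dtype=np.float64)
    axes = tuple(range(p.ndim - 1))

    inter = (p * y).sum(axis=axes)
    psum = p.sum(axis=axes)
    ysum = y.sum(axis=axes)
    num = 2.0 * inter + DICE_EPS
    den = psum + ysum + DICE_EPS
    dice_loss = 1.0 - (num / den).mean()
    # d(dice_loss)/dp_c(i) = -(1/C) * (2*y_c(i)*den_c - num_c) / den_c^2
    gp = -(2.0 * y * den - num) / (C * den**2)
    dz_dice = p * (gp - (gp * p).sum(axis=-1, keepdims=True))

    pix_w = y @ w
    wsum = pix_w.sum()
    ce = -(pix_w * (y * np.log(np.clip(p, 1e-12, 1.0))).sum(axis=-1)).sum() / wsum
    dz_ce = pix_w[..., None] * (p - y) / wsum

    lam = float(loss_lambda)
    loss = (1.0 - lam) * dice_loss + lam * ce
    grad = (1.0 - lam) * dz_dice + lam * dz_ce
    return float(loss), grad
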