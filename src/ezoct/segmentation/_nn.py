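"""Minimal NumPy CNN engine (NHWC layout) with manual backpropagation.

Implements exactly the layer set the segmentation network needs: 2-D "same"
convolution, batch normalization, leaky rectifier, 2x2 max pooling, 2x2
stride-2 transposed convolution, and an Adam optimizer.  Convolutions are
evaluated as a sum over kernel offsets of channel-axis matmuls — with
channels last each offset is a single contiguous BLAS GEMM, which keeps
memory proportional to the activation size and avoids layout shuffles.

All layers cache what backward needs during ``forward(..., training=True)``;
inference with ``training=False`` caches nothing.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "MaxPool2d",
    "ConvTranspose2d",
    "Adam",
]


class Layer:
    """Base class: parameters are (value, gradient) array pairs."""

    def parameters(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution with same (zero) padding, odd k, NHWC tensors.

    Weights are stored as (k, k, in_ch, out_ch) so the contribution of kernel
    offset (i, j) is ``xpad[:, i:i+H, j:j+W, :] @ W[i, j]``.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        if kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel_size
        fan_in = in_ch * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init, suits rectifier nets
        self.W = (rng.standard_normal((kernel_size, kernel_size, in_ch, out_ch)) * scale).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xpad: Optional[np.ndarray] = None

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, training=False):
        p = self.k // 2
        xpad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        N, H, W = x.shape[0], x.shape[1], x.shape[2]
        out_ch = self.W.shape[3]
        y = np.empty((N, H, W, out_ch), dtype=x.dtype)
        y[:] = self.b
        for i in range(self.k):
            for j in range(self.k):
                y += xpad[:, i : i + H, j : j + W, :] @ self.W[i, j]
        self._xpad = xpad if training else None
        return y

    def backward(self, grad):
        assert self._xpad is not None, "backward requires forward(training=True)"
        xpad = self._xpad
        N, H, W, _ = grad.shape
        p = self.k // 2
        dxpad = np.zeros_like(xpad)
        self.db[:] = grad.sum(axis=(0, 1, 2))
        cin = xpad.shape[3]
        g2 = grad.reshape(-1, grad.shape[3])
        for i in range(self.k):
            for j in range(self.k):
                xs = xpad[:, i : i + H, j : j + W, :].reshape(-1, cin)
                self.dW[i, j] = xs.T @ g2
                dxpad[:, i : i + H, j : j + W, :] += (g2 @ self.W[i, j].T).reshape(N, H, W, cin)
        self._xpad = None
        return dxpad[:, p : p + H, p : p + W, :] if p else dxpad


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32) -> None:
        self.gamma = np.ones(ch, dtype=dtype)
        self.beta = np.zeros(ch, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, inv_std = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        self.dbeta[:] = grad.sum(axis=(0, 1, 2))
        self.dgamma[:] = (grad * xhat).sum(axis=(0, 1, 2))
        return (self.gamma * inv_std) * (
            grad - self.dbeta / m - xhat * (self.dgamma / m)
        )


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1) -> None:
        self.slope = slope
        self._mask = None

    def forward(self, x, training=False):
        neg = x < 0
        if training:
            self._mask = neg
        return np.where(neg, x * self.slope, x)

    def backward(self, grad):
        out = np.where(self._mask, grad * self.slope, grad)
        self._mask = None
        return out


class MaxPool2d(Layer):
    """2x2, stride 2; ties resolve to the first (row-major) maximum."""

    def forward(self, x, training=False):
        N, H, W, C = x.shape
        xr = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4).reshape(
            N, H // 2, W // 2, C, 4
        )
        idx = xr.argmax(axis=-1)
        if training:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        N, H, W, C = self._shape
        out = np.zeros((N, H // 2, W // 2, C, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._idx[..., None], grad[..., None], axis=-1)
        self._idx = None
        return out.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
            N, H, W, C
        )


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling).

    Weights (4, in_ch, out_ch): one channel-matmul per output sub-position.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, dtype=np.float32) -> None:
        scale = np.sqrt(2.0 / (in_ch * 4))
        self.W = (rng.standard_normal((4, in_ch, out_ch)) * scale).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, training=False):
        if training:
            self._x = x
        N, H, W, C = x.shape
        out_ch = self.W.shape[2]
        y = np.empty((N, H, 2, W, 2, out_ch), dtype=x.dtype)
        for i in range(2):
            for j in range(2):
                y[:, :, i, :, j, :] = x @ self.W[2 * i + j]
        y = y.reshape(N, 2 * H, 2 * W, out_ch)
        y += self.b
        return y

    def backward(self, grad):
        x = self._x
        self._x = None
        N, H, W, C = x.shape
        g6 = grad.reshape(N, H, 2, W, 2, grad.shape[3])
        self.db[:] = grad.sum(axis=(0, 1, 2))
        x2 = x.reshape(-1, C)
        dx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                gij = np.ascontiguousarray(g6[:, :, i, :, j, :]).reshape(-1, grad.shape[3])
                self.dW[2 * i + j] = x2.T @ gij
                dx += (gij @ self.W[2 * i + j].T).reshape(N, H, W, C)
        return dx


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
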