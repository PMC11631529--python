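"""Minimal layer zoo with explicit forward/backward passes.

Arrays are NCHW float32 (float64 is supported for gradient checking).
Each layer keeps its parameters and gradients in dicts and caches the
activations it needs for the backward pass only when ``training=True`` —
evaluation-mode forwards (inference chains, bootstrap target passes) leave
no trace and therefore cannot leak gradients.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n, c, h, w, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    """Same-padding 2-D convolution (odd kernel)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        assert kernel % 2 == 1
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.params["W"] = rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)).astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        k = self.kernel
        pad = k // 2
        cols = _im2col(x, k, pad)
        w2 = self.params["W"].reshape(self.out_ch, -1)
        out = np.matmul(w2, cols) + self.params["b"][None, :, None]
        if training:
            self._cache = (cols, x.shape)
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, dout):
        cols, xshape = self._cache
        self._cache = None
        n, c, h, w = xshape
        k = self.kernel
        df = dout.reshape(n, self.out_ch, h * w)
        self.grads["W"] += np.matmul(df, cols.transpose(0, 2, 1)).sum(0).reshape(
            self.params["W"].shape
        )
        self.grads["b"] += df.sum((0, 2))
        w2 = self.params["W"].reshape(self.out_ch, -1)
        dcols = np.matmul(w2.T, df)
        return _col2im(dcols, xshape, k, k // 2)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(ch, dtype=dtype)
        self.params["beta"] = np.zeros(ch, dtype=dtype)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.zero_grad()

    def forward(self, x, training=False):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(self.running_var.dtype)
            self._cache = (xhat, inv_std)
            return g * xhat + b
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * inv_std[None, :, None, None]
        return g * xhat + b

    def backward(self, dout):
        xhat, inv_std = self._cache
        self._cache = None
        n, c, h, w = dout.shape
        m = n * h * w
        self.grads["gamma"] += (dout * xhat).sum((0, 2, 3))
        self.grads["beta"] += dout.sum((0, 2, 3))
        dxhat = dout * self.params["gamma"][None, :, None, None]
        s1 = dxhat.sum((0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum((0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, training=False):
        if training:
            self._cache = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        mask = self._cache
        self._cache = None
        return dout * mask


class Sigmoid(Layer):
    def forward(self, x, training=False):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        if training:
            self._cache = out
        return out

    def backward(self, dout):
        out = self._cache
        self._cache = None
        return dout * out * (1.0 - out)


class MaxPool2d(Layer):
    """2×2 max pooling; input spatial dims must be even."""

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if training:
            mask = xr == out[:, :, :, None, :, None]
            counts = mask.sum((3, 5), keepdims=True)
            self._cache = (mask, counts, x.shape)
        return out

    def backward(self, dout):
        mask, counts, xshape = self._cache
        self._cache = None
        n, c, h, w = xshape
        dxr = mask * (dout[:, :, :, None, :, None] / counts)
        return dxr.reshape(n, c, h, w)


class Upsample2x(Layer):
    """Nearest-neighbour 2× upsampling."""

    def forward(self, x, training=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum((3, 5))
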