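"""Minimal NumPy neural-network primitives with exact backpropagation.

Supports the small hierarchical classifiers used as surrogates for a deep
convolutional network: 2D convolution (stride 1, "same" padding), 2x2 max
pooling, dense layers, ReLU and softmax.  All layers implement ``forward``
(caching what ``backward`` needs) and ``backward`` (returning the gradient
with respect to the input and accumulating parameter gradients).

Array layout is NCHW for spatial tensors and (N, D) for dense tensors.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "MaxPool2", "Dense", "ReLU", "Flatten", "softmax"]


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    # x: (N, C, H, W) -> (N, H*W, C*k*k) patches for stride-1 same conv
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N, C, H, W, k, k
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, stride 1, zero padding preserving spatial size."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * k * k
        self.k, self.pad = k, k // 2
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in))
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x):
        self._xshape = x.shape
        self._cols = _im2col(x, self.k, self.pad)  # N, HW, CKK
        n, _, h, w = x.shape
        out = self._cols @ self.params["W"].T + self.params["b"]  # N, HW, F
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, dout):
        n, f, h, w = dout.shape
        dflat = dout.reshape(n, f, h * w).transpose(0, 2, 1)  # N, HW, F
        self.grads["W"] = np.einsum("npf,npc->fc", dflat, self._cols)
        self.grads["b"] = dflat.sum(axis=(0, 1))
        dcols = dflat @ self.params["W"]  # N, HW, CKK
        return _col2im(dcols, self._xshape, self.k, self.pad)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; ties split their gradient evenly."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._counts = self._mask.sum(axis=(3, 5), keepdims=True)
        self._xshape = x.shape
        return out

    def backward(self, dout):
        d = self._mask * (dout[:, :, :, None, :, None] / self._counts)
        n, c, h, w = self._xshape
        return d.reshape(n, c, h, w)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_dim), (out_dim, in_dim))
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)
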