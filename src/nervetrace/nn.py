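"""Minimal NumPy neural-network engine for encoder-decoder segmentation.

Implements exactly the layers the U-Net and SegNet variants need --
same-padding convolution, 2x2 max-pooling that records argmax positions,
index unpooling, 2x2 stride-2 transposed convolution, ReLU and a logistic
head -- each with an explicit forward/backward pass, plus an Adam optimizer.

Tensors are laid out NHWC (batch, rows, cols, channels).  Convolutions are
evaluated as a sum of k*k shifted matrix products rather than an im2col
buffer, which keeps the memory footprint proportional to the activations.
Gradients accumulate into ``Param.grad`` until ``Adam.zero_grad`` clears
them; a layer instance caches its forward activations, so one instance
serves one forward/backward pair at a time.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "MaxUnpool2d",
    "ReLU",
    "Sigmoid",
    "ConvBlock",
    "Adam",
]


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, zero same-padding, He-initialised weights."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 dtype=np.float32, init_scale: float = 1.0):
        # init_scale=0 zero-initialises (used for the sigmoid head so the
        # untrained network starts at p=0.5 everywhere, loss ln 2)
        fan_in = in_ch * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, in_ch, out_ch))
        self.w = Param((init_scale * w).astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self.k = k
        self.pad = k // 2

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        k, p = self.k, self.pad
        N, H, W, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xp = xp
        self._hw = (H, W)
        y = np.zeros((N, H, W, self.w.value.shape[3]), dtype=x.dtype)
        for di in range(k):
            for dj in range(k):
                y += xp[:, di:di + H, dj:dj + W, :] @ self.w.value[di, dj]
        return y + self.b.value

    def backward(self, gy):
        k, p = self.k, self.pad
        H, W = self._hw
        xp = self._xp
        gxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di:di + H, dj:dj + W, :]
                self.w.grad[di, dj] += np.tensordot(xs, gy, axes=([0, 1, 2], [0, 1, 2]))
                gxp[:, di:di + H, dj:dj + W, :] += gy @ self.w.value[di, dj].T
        self.b.grad += gy.sum(axis=(0, 1, 2))
        self._xp = None
        if p:
            return gxp[:, p:-p, p:-p, :]
        return gxp


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (learned x2 upsampling).

    Kernel and stride coincide, so every output pixel receives exactly one
    kernel tap and the operation needs no overlap handling.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        w = rng.normal(0.0, np.sqrt(2.0 / in_ch), size=(in_ch, out_ch, 2, 2))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        t = np.tensordot(x, self.w.value, axes=([3], [0]))  # N,H,W,O,2,2
        N, H, W, O = t.shape[:4]
        y = t.transpose(0, 1, 4, 2, 5, 3).reshape(N, 2 * H, 2 * W, O)
        return y + self.b.value

    def backward(self, gy):
        N, H2, W2, O = gy.shape
        H, W = H2 // 2, W2 // 2
        gt = gy.reshape(N, H, 2, W, 2, O).transpose(0, 1, 3, 5, 2, 4)  # N,H,W,O,2,2
        self.w.grad += np.tensordot(self._x, gt, axes=([0, 1, 2], [0, 1, 2]))
        self.b.grad += gy.sum(axis=(0, 1, 2))
        gx = np.tensordot(gt, self.w.value, axes=([3, 4, 5], [1, 2, 3]))
        self._x = None
        return gx


def _scatter_windows(values: np.ndarray, idx: np.ndarray,
                     out_shape: tuple) -> np.ndarray:
    """Place ``values`` back into 2x2 windows of ``out_shape`` at ``idx``."""
    N, H, W, C = out_shape
    g4 = np.zeros((N, H // 2, W // 2, C, 4), dtype=values.dtype)
    np.put_along_axis(g4, idx[..., None], values[..., None], axis=4)
    return (g4.reshape(N, H // 2, W // 2, C, 2, 2)
              .transpose(0, 1, 4, 2, 5, 3)
              .reshape(N, H, W, C))


def _window_view(x: np.ndarray) -> np.ndarray:
    """Reshape (N,H,W,C) into (N,H/2,W/2,C,4) windows of 2x2 blocks."""
    N, H, W, C = x.shape
    return (x.reshape(N, H // 2, 2, W // 2, 2, C)
             .transpose(0, 1, 3, 5, 2, 4)
             .reshape(N, H // 2, W // 2, C, 4))


class MaxPool2d(Layer):
    """2x2 max-pooling, stride 2; records the argmax within each window.

    Ties resolve to the first maximum in row-major window order, matching
    ``argmax``.  The recorded indices drive both the pooling gradient and
    SegNet-style unpooling.
    """

    def forward(self, x):
        xr = _window_view(x)
        self.idx = xr.argmax(axis=4)
        self.in_shape = x.shape
        return np.take_along_axis(xr, self.idx[..., None], axis=4)[..., 0]

    def backward(self, gy):
        return _scatter_windows(gy, self.idx, self.in_shape)


class MaxUnpool2d(Layer):
    """Index unpooling: routes each value to the argmax position its paired
    :class:`MaxPool2d` recorded, zero elsewhere."""

    def __init__(self, pool: MaxPool2d):
        self.pool = pool

    def forward(self, x):
        return _scatter_windows(x, self.pool.idx, self.pool.in_shape)

    def backward(self, gy):
        gr = _window_view(gy)
        return np.take_along_axis(gr, self.pool.idx[..., None], axis=4)[..., 0]


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, gy):
        return gy * self._m


class Sigmoid(Layer):
    """Logistic head; outputs are clipped into [1e-7, 1 - 1e-7] so they stay
    strictly inside (0, 1) even when float32 saturates."""

    EPS = 1e-7

    def forward(self, x):
        s = expit(x)
        self._s = s
        return np.clip(s, self.EPS, 1.0 - self.EPS)

    def backward(self, gy):
        return gy * self._s * (1.0 - self._s)


class ConvBlock(Layer):
    """Two same-padding k x k convolutions, each followed by ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 k: int = 3, dtype=np.float32):
        self.layers = [
            Conv2d(in_ch, out_ch, k, rng, dtype),
            ReLU(),
            Conv2d(out_ch, out_ch, k, rng, dtype),
            ReLU(),
        ]

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, gy):
        for lay in reversed(self.layers):
            gy = lay.backward(gy)
        return gy


class Adam:
    """Adam optimizer over a flat parameter list.

    Defaults: lr 1e-3, betas (0.9, 0.999), eps 1e-7.
    """

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-7):
        self.params_ = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params_:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params_, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
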