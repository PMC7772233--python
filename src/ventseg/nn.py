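"""Minimal CPU neural-network layers with analytic gradients.

The segmentation model is small enough (64x64 slices, a handful of
convolutions) that a hand-rolled numpy stack is practical: convolutions run
as im2col matrix products, and every backward pass is itself expressed as a
convolution or a tensor contraction, so no scatter-add appears on the hot
path.  Layers follow the usual forward/backward protocol: ``forward`` caches
what ``backward`` needs; ``backward`` receives the upstream gradient and
returns the gradient with respect to the layer input while accumulating
parameter gradients in ``.grads``.

Array layout is NCHW throughout this module.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "PixelShuffle",
    "softmax",
    "softmax_backward",
    "Adam",
    "he_init",
]


def he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """He-normal initialization for ReLU networks; fan-in from shape[1:]."""
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)


def _dilate(x: np.ndarray, stride: int) -> np.ndarray:
    """Insert stride-1 zeros between rows/cols of an NCHW tensor."""
    if stride == 1:
        return x
    n, c, h, w = x.shape
    out = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=x.dtype)
    out[:, :, ::stride, ::stride] = x
    return out


def _conv_matmul(x: np.ndarray, w: np.ndarray, stride: int, pad: int):
    """Correlate NCHW input with OIHW kernel; returns (y, cols, xp_shape).

    cols is the (N*OH*OW, I*KH*KW) im2col matrix, cached for the weight
    gradient.
    """
    kh, kw = w.shape[2], w.shape[3]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: N, I, OH, OW, KH, KW -> N, OH, OW, I, KH, KW
    n, i, oh, ow = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, i * kh * kw
    )
    y = cols @ w.reshape(w.shape[0], -1).T
    # returned as a strided NCHW view; downstream elementwise ops and pads
    # accept it, avoiding one full copy per convolution
    y = y.reshape(n, oh, ow, w.shape[0]).transpose(0, 3, 1, 2)
    return y, cols, (oh, ow)


class Conv2d:
    """2-D correlation with bias.  kernel: (out, in, kh, kw)."""

    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int,
                 kernel: int = 3, stride: int = 1, pad: int | None = None):
        self.stride = stride
        self.pad = (kernel // 2) if pad is None else pad
        self.params = {
            "w": he_init(rng, (out_ch, in_ch, kernel, kernel)),
            "b": np.zeros(out_ch, dtype=np.float64),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.params["w"]
        if x.shape[1] != w.shape[1]:
            raise ValueError(
                f"Conv2d expected {w.shape[1]} input channels, got {x.shape[1]}"
            )
        y, cols, _ = _conv_matmul(x, w, self.stride, self.pad)
        self._cache = (cols, x.shape)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        w = self.params["w"]
        o = w.shape[0]
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(-1, o)
        self.grads["w"] += (dy_mat.T @ cols).reshape(w.shape)
        self.grads["b"] += dy_mat.sum(axis=0)
        # dx as a full correlation of the (dilated) upstream gradient with the
        # spatially flipped, channel-transposed kernel.  When stride does not
        # divide H + 2p - k evenly, the transposed conv needs extra zeros on
        # the bottom/right so trailing input rows/cols get their gradient.
        kh, kw = w.shape[2], w.shape[3]
        s, p = self.stride, self.pad
        n, c, h, wd = x_shape
        fp = kh - 1 - p
        assert fp >= 0, "backward requires pad <= kernel - 1"
        eh, ew = (h + 2 * p - kh) % s, (wd + 2 * p - kw) % s
        dyd = _dilate(dy, s)
        dyd = np.pad(dyd, ((0, 0), (0, 0), (fp, fp + eh), (fp, fp + ew)))
        w_flip = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        dx, _, _ = _conv_matmul(dyd, w_flip, 1, 0)
        return dx


class BatchNorm2d:
    """Channel-wise batch normalization with running statistics.

    Training mode normalizes by batch statistics and updates running
    mean/variance; eval mode uses the running statistics.  The running
    buffers are saved in checkpoints but are not optimizer slots.
    """

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(ch, dtype=np.float64),
            "beta": np.zeros(ch, dtype=np.float64),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.buffers = {
            "running_mean": np.zeros(ch, dtype=np.float64),
            "running_var": np.ones(ch, dtype=np.float64),
        }
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] *= 1 - m
            self.buffers["running_mean"] += m * mu
            self.buffers["running_var"] *= 1 - m
            self.buffers["running_var"] += m * var
        else:
            mu = self.buffers["running_mean"].astype(x.dtype)
            var = self.buffers["running_var"].astype(x.dtype)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar.astype(x.dtype))
        return (g * xhat + b).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        axes = (0, 2, 3)
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        g = self.params["gamma"].astype(dy.dtype)[None, :, None, None]
        if not self.training:
            return dy * g * ivar[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dy.sum(axis=axes)[None, :, None, None]
        s2 = (dy * xhat).sum(axis=axes)[None, :, None, None]
        return (g * ivar[None, :, None, None] / n) * (n * dy - s1 - xhat * s2)


class ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2d:
    """Max pooling (used only by the deep residual encoder variant)."""

    params: dict = {}
    grads: dict = {}

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, oh, ow = win.shape[:4]
        flat = win.reshape(n, c, oh, ow, k * k)
        self._arg = flat.argmax(axis=-1)
        self._x_shape, self._xp_shape = x.shape, xp.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, c, oh, ow = dy.shape
        dxp = np.zeros(self._xp_shape, dtype=dy.dtype)
        ih = (self._arg // k) + s * np.arange(oh)[None, None, :, None]
        iw = (self._arg % k) + s * np.arange(ow)[None, None, None, :]
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, ih, iw), dy)
        h, w = self._x_shape[2], self._x_shape[3]
        return dxp[:, :, p : p + h, p : p + w]


class PixelShuffle:
    """Depth-to-space rearrangement by factor r (row-major sub-pixel order).

    Input (N, C*r*r, H, W) -> output (N, C, rH, rW); the r*r channels of each
    pixel tile its r x r output block, channel index (i % r) * r + (j % r).
    """

    params: dict = {}
    grads: dict = {}

    def __init__(self, r: int):
        self.r = r

    def forward(self, x: np.ndarray) -> np.ndarray:
        r = self.r
        n, crr, h, w = x.shape
        if crr % (r * r):
            raise ValueError(f"channels {crr} not divisible by r^2={r * r}")
        c = crr // (r * r)
        self._in_shape = x.shape
        y = x.reshape(n, c, r, r, h, w).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(y).reshape(n, c, h * r, w * r)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        r = self.r
        n, c, rh, rw = dy.shape
        h, w = rh // r, rw // r
        dx = dy.reshape(n, c, h, r, w, r).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(dx).reshape(self._in_shape)


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray, axis: int = 1) -> np.ndarray:
    """Gradient w.r.t. logits given probabilities p and dL/dp."""
    inner = (dp * p).sum(axis=axis, keepdims=True)
    return p * (dp - inner)


class SGD:
    """Plain stochastic gradient descent (no momentum)."""

    def __init__(self, layers, lr: float = 1e-2):
        self.slots = [
            (layer.params, layer.grads, key)
            for layer in layers
            for key in layer.params
        ]
        self.lr = lr

    def zero_grad(self) -> None:
        for _, g, k in self.slots:
            g[k][...] = 0.0

    def step(self) -> None:
        for p, g, k in self.slots:
            p[k] -= self.lr * g[k]


class Adam:
    """Adam over a flat list of (params, grads) dicts from layers."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.slots = [
            (layer.params, layer.grads, key)
            for layer in layers
            for key in layer.params
        ]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p[k]) for p, _, k in self.slots]
        self.v = [np.zeros_like(p[k]) for p, _, k in self.slots]

    def zero_grad(self) -> None:
        for _, g, k in self.slots:
            g[k][...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, (p, g, k) in enumerate(self.slots):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g[k]
            self.v[i] = b2 * self.v[i] + (1 - b2) * g[k] ** 2
            p[k] -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
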