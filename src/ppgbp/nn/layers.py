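"""Layers with explicit forward/backward passes on numpy arrays.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.grad`` during ``backward``,
returning the gradient with respect to its input.  Feature maps are
``(batch, channels, length)``; fully connected activations are
``(batch, features)``.

Convolutions use "same" padding semantics: the output length is
``ceil(length / stride)`` regardless of kernel size.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "DepthwiseConv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Linear",
    "SEBlock",
    "conv_out_len",
]


def conv_out_len(length: int, stride: int) -> int:
    """Output length of a same-padded strided convolution."""
    return -(-length // stride)  # ceil division


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int]:
    out = conv_out_len(length, stride)
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class: parameter bookkeeping and train/eval state."""

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trained state (e.g. batch-norm running statistics)."""
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class Conv1d(Layer):
    """Standard 1-D convolution (cross-correlation), same padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False):
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"Conv1d expects {self.in_ch} input channels, got {x.shape[1]}"
            )
        n, _, length = x.shape
        left, right = _same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        cols = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        # (N, C, Lo, K) x (D, C, K) -> (N, D, Lo)
        out_len = cols.shape[2]
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            n * out_len, self.in_ch * self.kernel
        )
        wmat = self.w.data.reshape(self.out_ch, -1)
        y = (cols2 @ wmat.T).reshape(n, out_len, self.out_ch).transpose(0, 2, 1)
        if self.b is not None:
            y = y + self.b.data[:, None]
        self._cache = (cols2, x.shape, left, out_len)
        return np.ascontiguousarray(y)

    def backward(self, gy):
        cols2, x_shape, left, out_len = self._cache
        n, _, length = x_shape
        g2 = np.ascontiguousarray(gy.transpose(0, 2, 1)).reshape(n * out_len, self.out_ch)
        self.w.grad += (g2.T @ cols2).reshape(self.w.data.shape)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2))
        gcols2 = g2 @ self.w.data.reshape(self.out_ch, -1)
        gcols = gcols2.reshape(n, out_len, self.in_ch, self.kernel).transpose(0, 2, 1, 3)
        total = _same_pad(length, self.kernel, self.stride)
        gxp = np.zeros((n, self.in_ch, length + total[0] + total[1]), dtype=gy.dtype)
        for j in range(self.kernel):
            gxp[:, :, j : j + self.stride * out_len : self.stride] += gcols[:, :, :, j]
        return gxp[:, :, left : left + length]


class DepthwiseConv1d(Layer):
    """Per-channel (depthwise) 1-D convolution, same padding."""

    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, math.sqrt(2.0 / kernel), size=(channels, kernel))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(channels, dtype=dtype)) if bias else None
        self.channels, self.kernel, self.stride = channels, kernel, stride
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False):
        if x.shape[1] != self.channels:
            raise ValueError(
                f"DepthwiseConv1d expects {self.channels} channels, got {x.shape[1]}"
            )
        n, _, length = x.shape
        left, right = _same_pad(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        cols = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        y = np.einsum("nclk,ck->ncl", cols, self.w.data, optimize=True)
        if self.b is not None:
            y = y + self.b.data[:, None]
        self._cache = (cols, x.shape, left)
        return y

    def backward(self, gy):
        cols, x_shape, left = self._cache
        n, _, length = x_shape
        out_len = gy.shape[2]
        self.w.grad += np.einsum("nclk,ncl->ck", cols, gy, optimize=True)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2))
        gcols = gy[:, :, :, None] * self.w.data[None, :, None, :]
        total = _same_pad(length, self.kernel, self.stride)
        gxp = np.zeros((n, self.channels, length + total[0] + total[1]), dtype=gy.dtype)
        for j in range(self.kernel):
            gxp[:, :, j : j + self.stride * out_len : self.stride] += gcols[:, :, :, j]
        return gxp[:, :, left : left + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps, self.channels = momentum, eps, channels
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None]) * inv_std[:, None]
        y = self.gamma.data[:, None] * xhat + self.beta.data[:, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return y

    def backward(self, gy):
        xhat, inv_std, training, shape = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2))
        self.beta.grad += gy.sum(axis=(0, 2))
        gxhat = gy * self.gamma.data[:, None]
        if not training:
            return gxhat * inv_std[:, None]
        m = shape[0] * shape[2]
        # standard batch-norm gradient with batch statistics
        sum_g = gxhat.sum(axis=(0, 2), keepdims=True)
        sum_gx = (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[:, None] / m) * (m * gxhat - sum_g - xhat * sum_gx)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool1d(Layer):
    """Max pooling with explicit padding (pad value -inf)."""

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, training=False):
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)),
                    constant_values=-np.inf)
        cols = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        idx = cols.argmax(axis=3)
        y = np.take_along_axis(cols, idx[..., None], axis=3)[..., 0]
        self._cache = (idx, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, gy):
        idx, (n, c, length) = self._cache
        out_len = gy.shape[2]
        gxp = np.zeros((n, c, length + 2 * self.pad), dtype=gy.dtype)
        pos = self.stride * np.arange(out_len)[None, None, :] + idx  # in padded coords
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(gxp, (ni, ci, pos), gy)
        return gxp[:, :, self.pad : self.pad + length]


class GlobalAvgPool1d(Layer):
    """(N, C, L) -> (N, C) channel means."""

    def forward(self, x, training=False):
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy):
        return np.repeat(gy[:, :, None], self._len, axis=2) / self._len


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, math.sqrt(2.0 / in_features),
                       size=(out_features, in_features))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(out_features, dtype=dtype))
        self.in_features, self.out_features = in_features, out_features

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, gy):
        self.w.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.data


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: per-channel global average over the feature-map width.
    Excite: bottleneck of two fully connected layers (reduction ``r``) with
    ReLU between them and a sigmoid on the output, yielding one weight in
    (0, 1) per channel.  Scale: each channel is multiplied by its weight.
    Output shape equals input shape.
    """

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng=rng, dtype=dtype)
        self.channels, self.reduction, self.hidden = channels, reduction, hidden

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def attention(self, x: np.ndarray) -> np.ndarray:
        """Channel weights s in (0,1)^(N x C) for a feature map (no cache)."""
        z = x.mean(axis=2)
        a = self.fc1.forward(z)
        h = np.maximum(a, 0.0)
        return _sigmoid(self.fc2.forward(h))

    def forward(self, x, training=False):
        length = x.shape[2]
        z = x.mean(axis=2)                      # squeeze
        a = self.fc1.forward(z)
        h = np.maximum(a, 0.0)
        logits = self.fc2.forward(h)
        s = _sigmoid(logits)                    # excite
        y = x * s[:, :, None]                   # scale
        self._cache = (x, s, h, a, length)
        return y

    def backward(self, gy):
        x, s, h, a, length = self._cache
        gx = gy * s[:, :, None]
        gs = (gy * x).sum(axis=2)
        glogits = gs * s * (1.0 - s)
        gh = self.fc2.backward(glogits)
        ga = gh * (a > 0)
        gz = self.fc1.backward(ga)
        gx += gz[:, :, None] / length
        return gx
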