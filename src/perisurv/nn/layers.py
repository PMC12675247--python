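"""Layers with explicit forward/backward passes.

Every layer follows the same tiny protocol: ``forward(x, training)`` caches
what backward needs; ``backward(dy)`` returns ``dx`` and accumulates
parameter gradients in ``param.grad``.  Parameters are held in
:class:`Param` objects so the optimizer can iterate them generically.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv3d", "BatchNorm", "ReLU", "Tanh", "Sigmoid",
    "MaxPool3d", "GlobalAvgPool", "Dense", "Dropout", "SEBlock",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "weight_decay")

    def __init__(self, value: np.ndarray, weight_decay: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.weight_decay = weight_decay  # L2 applies to weights, not biases/BN


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _same_pad(n: int, k: int, s: int) -> tuple[int, int]:
    """TensorFlow-style SAME padding: output size = ceil(n / s)."""
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2


class Conv3d(Layer):
    """3D convolution, SAME padding, via im2col + matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel, kernel))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out), weight_decay=False)
        self.kernel = kernel
        self.stride = stride
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        n, c, d, h, w_ = x.shape
        k, s = self.kernel, self.stride
        pads = [_same_pad(dim, k, s) for dim in (d, h, w_)]
        xp = np.pad(x, [(0, 0), (0, 0)] + pads)
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        # win: (n, c, D', H', W', k, k, k) -> cols (n*P, c*k^3)
        do, ho, wo = win.shape[2:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, c * k**3)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        out = cols @ wmat.T + self.b.value
        out = out.reshape(n, do, ho, wo, -1).transpose(0, 4, 1, 2, 3)
        self._cache = (x.shape, xp.shape, pads, cols, (do, ho, wo))
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dy):
        x_shape, xp_shape, pads, cols, (do, ho, wo) = self._cache
        n, c, d, h, w_ = x_shape
        k, s = self.kernel, self.stride
        c_out = self.w.value.shape[0]
        dy_cols = dy.transpose(0, 2, 3, 4, 1).reshape(-1, c_out)
        wmat = self.w.value.reshape(c_out, -1)
        self.w.grad += (dy_cols.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dy_cols.sum(axis=0)
        dcols = (dy_cols @ wmat).reshape(n, do, ho, wo, c, k, k, k)
        # col2im: scatter-add each kernel offset back onto the padded grid
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for a in range(k):
            for bb in range(k):
                for cc in range(k):
                    dxp[:, :, a : a + do * s : s, bb : bb + ho * s : s, cc : cc + wo * s : s] += (
                        dcols[:, :, :, :, :, a, bb, cc].transpose(0, 4, 1, 2, 3)
                    )
        sl = tuple(slice(p[0], dim + p[0]) for p, dim in zip(pads, (d, h, w_)))
        return dxp[(slice(None), slice(None)) + sl]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), weight_decay=False)
        self.beta = Param(np.zeros(channels), weight_decay=False)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) + tuple(range(2, x.ndim))

    def forward(self, x, training=False):
        axes = self._axes(x)
        shape = [1, x.shape[1]] + [1] * (x.ndim - 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, shape, axes, x.shape)
        return (self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)).astype(np.float32)

    def backward(self, dy):
        xhat, inv, shape, axes, x_shape = self._cache
        m = np.prod([x_shape[a] for a in axes])
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv.reshape(shape)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y.astype(np.float32)

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y.astype(np.float32)

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool3d(Layer):
    """Max pooling, SAME padding (padded entries are -inf, never selected)."""

    def __init__(self, kernel: int = 3, stride: int = 2):
        self.kernel = kernel
        self.stride = stride

    def forward(self, x, training=False):
        n, c, d, h, w_ = x.shape
        k, s = self.kernel, self.stride
        pads = [_same_pad(dim, k, s) for dim in (d, h, w_)]
        xp = np.pad(x, [(0, 0), (0, 0)] + pads, constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        do, ho, wo = win.shape[2:5]
        flat = win.reshape(n, c, do, ho, wo, k**3)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (xp.shape, pads, arg, (do, ho, wo), x.shape)
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dy):
        xp_shape, pads, arg, (do, ho, wo), x_shape = self._cache
        n, c, d, h, w_ = x_shape
        k, s = self.kernel, self.stride
        dxp = np.zeros(xp_shape, dtype=np.float32)
        ai, bi, ci = np.unravel_index(arg, (k, k, k))
        ni, cj, di, hi, wi = np.indices(arg.shape, sparse=False)
        np.add.at(dxp, (ni, cj, di * s + ai, hi * s + bi, wi * s + ci), dy)
        sl = tuple(slice(p[0], dim + p[0]) for p, dim in zip(pads, (d, h, w_)))
        return dxp[(slice(None), slice(None)) + sl]


class GlobalAvgPool(Layer):
    """(N, C, D, H, W) -> (N, C)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(np.float32)

    def backward(self, dy):
        n, c, d, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None, None], self._shape) / (d * h * w)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out), weight_decay=False)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return (x @ self.w.value + self.b.value).astype(np.float32)

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; the mask comes from the network's training RNG."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class SEBlock(Layer):
    """Squeeze-and-excitation channel recalibration.

    squeeze = per-channel spatial mean; excitation = sigmoid(FC2(relu(FC1)))
    with bottleneck width max(C / ratio, 1); output = input * weights.
    """

    def __init__(self, channels: int, ratio: int = 64, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(channels // ratio, 1)
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)
        self.relu = ReLU()
        self.sigmoid = Sigmoid()

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, x, training=False):
        n, c = x.shape[:2]
        squeeze = x.mean(axis=(2, 3, 4))
        wgt = self.sigmoid.forward(self.fc2.forward(self.relu.forward(self.fc1.forward(squeeze, training), training), training), training)
        self._cache = (x, wgt)
        return (x * wgt[:, :, None, None, None]).astype(np.float32)

    def backward(self, dy):
        x, wgt = self._cache
        spatial = np.prod(x.shape[2:])
        dwgt = (dy * x).sum(axis=(2, 3, 4))
        dsqueeze = self.fc1.backward(self.relu.backward(self.fc2.backward(self.sigmoid.backward(dwgt))))
        dx = dy * wgt[:, :, None, None, None]
        dx += np.broadcast_to(dsqueeze[:, :, None, None, None], x.shape) / spatial
        return dx.astype(np.float32)
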