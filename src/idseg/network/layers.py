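"""NumPy/Numba autodiff layers for the 2D view networks.

Activations use NCHW layout ``(batch, channels, height, width)`` in float32;
the width axis stays contiguous so the Numba convolution kernels vectorize.
Each layer caches what its backward needs; ``backward`` must be called with
the gradient of the loss w.r.t. the layer output right after the
corresponding ``forward`` (the single shared PReLU keeps a LIFO stack so one
instance can serve several call sites inside a block).
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from ._kernels import (bn_bwd, bn_fwd_finish, conv_bwd, conv_fwd, pool_fwd,
                       prelu_bwd, prelu_fwd, unpool_fwd)

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "PReLU",
    "MaxPool2d",
    "MaxUnpool2d",
    "Dropout",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = True
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """Stride-1, same-padded 2D convolution with bias (weights (F, C, k, k))."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv"):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = kernel * kernel * in_ch
        bound = float(np.sqrt(1.0 / fan_in))  # Kaiming-uniform style init
        w = rng.uniform(-bound, bound, size=(out_ch, in_ch, kernel, kernel))
        b = rng.uniform(-bound, bound, size=(out_ch,))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(b, f"{name}.bias")
        self._xp: Optional[np.ndarray] = None
        self._in_shape = None

    def params(self) -> List[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = np.empty((n, self.out_ch, h, w), dtype=np.float32)
        conv_fwd(xp, self.weight.value, self.bias.value, out)
        if train:
            self._xp, self._in_shape = xp, x.shape
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        k = self.kernel
        p = k // 2
        dxp = np.zeros_like(self._xp)
        conv_bwd(self._xp, self.weight.value, np.ascontiguousarray(g),
                 dxp, self.weight.grad, self.bias.grad)
        self._xp = None
        if p:
            return np.ascontiguousarray(dxp[:, :, p:p + h, p:p + w])
        return dxp


class BatchNorm2d:
    """Batch normalization over (N, H, W) per channel, with running stats."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(ch), f"{name}.weight")
        self.beta = Param(np.zeros(ch), f"{name}.bias")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum = np.float32(momentum)
        self.eps = np.float32(eps)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cview = (1, -1, 1, 1)
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float32)
            var = x.var(axis=(0, 2, 3), dtype=np.float32)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = np.float32(1.0) / np.sqrt(var + self.eps)
            out = np.empty_like(x)
            xhat = np.empty_like(x)
            bn_fwd_finish(x, mean, inv, self.gamma.value, self.beta.value, out, xhat)
            self._cache = (xhat, inv)
            return out
        mean, var = self.running_mean, self.running_var
        inv = np.float32(1.0) / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(cview)) * inv.reshape(cview)
        return xhat * self.gamma.value.reshape(cview) + self.beta.value.reshape(cview)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = np.float32(g.shape[0] * g.shape[2] * g.shape[3])
        ch = xhat.shape[1]
        dgamma = np.empty(ch, dtype=np.float32)
        dbeta = np.empty(ch, dtype=np.float32)
        coef = self.gamma.value * inv / m
        dx = np.empty_like(g)
        bn_bwd(np.ascontiguousarray(g), xhat, coef, dgamma, dbeta, m, dx)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        self._cache = None
        return dx


class PReLU:
    """Single-parameter PReLU, shareable across several call sites."""

    def __init__(self, init: float = 0.25, name: str = "prelu"):
        self.alpha = Param(np.array([init]), f"{name}.weight")
        self._stack: List = []

    def params(self) -> List[Param]:
        return [self.alpha]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a = np.float32(self.alpha.value[0])
        x = np.ascontiguousarray(x)
        out = np.empty_like(x)
        prelu_fwd(x, a, out)
        if train:
            self._stack.append(x)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._stack.pop()
        a = np.float32(self.alpha.value[0])
        dx = np.empty_like(x)
        da = prelu_bwd(x, np.ascontiguousarray(g), a, dx)
        self.alpha.grad += np.float32(da)
        return dx


class MaxPool2d:
    """2x2 stride-2 max pooling that records argmax corners for unpooling."""

    def forward(self, x: np.ndarray, train: bool):
        n, c, h, w = x.shape
        out = np.empty((n, c, h // 2, w // 2), dtype=np.float32)
        idx = np.empty((n, c, h // 2, w // 2), dtype=np.int8)
        pool_fwd(np.ascontiguousarray(x), out, idx)
        return out, idx


class MaxUnpool2d:
    """Place values back at their recorded 2x2 argmax corners."""

    @staticmethod
    def scatter(x: np.ndarray, idx: np.ndarray, out_shape) -> np.ndarray:
        out = np.zeros(out_shape, dtype=np.float32)
        unpool_fwd(np.ascontiguousarray(x), idx, out)
        return out

    @staticmethod
    def gather(g: np.ndarray, idx: np.ndarray) -> np.ndarray:
        n, c, h, w = g.shape
        out = np.empty((n, c, h // 2, w // 2), dtype=np.float32)
        pool_like = np.ascontiguousarray(g)
        _gather(pool_like, idx, out)
        return out


def _gather(g, idx, out):
    # thin vectorized gather: pick the corner recorded in idx
    n, c, h2, w2 = out.shape
    gr = g.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = np.ascontiguousarray(gr).reshape(n, c, h2, w2, 4)
    out[...] = np.take_along_axis(v, idx[..., None].astype(np.intp), axis=-1)[..., 0]


class Dropout:
    """Inverted dropout with an explicit generator for reproducibility."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = float(rate)
        self.rng = rng
        self._mask = None

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask
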