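"""Minimal NumPy neural-network engine used by the TRL estimators.

Implements exactly the pieces the two estimator architectures need: strided
2-D convolution (im2col + BLAS matmul), nearest-neighbour upsampling, fully
connected layers, ReLU / sigmoid / softplus, global average pooling, and an
Adam optimizer.  Forward passes cache what the hand-written backward passes
need; gradients are verified against numeric differentiation in the test
suite.  All arrays are float32, NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "Linear",
    "ReLU",
    "UpsampleNearest2",
    "Adam",
    "sigmoid",
    "softplus",
    "global_avg_pool",
]

DTYPE = np.float32


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv2d(Layer):
    """k x k convolution, stride s, symmetric zero padding (default "same" k//2)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        self.W = Param(f"{name}.W", _he_init(rng, (c_out, c_in * k * k), c_in * k * k))
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=DTYPE))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, c, _, _ = xp.shape
        k, s = self.k, self.stride
        cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
        return cols.reshape(n, c * k * k, ho * wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = self._im2col(xp, ho, wo)
        out = np.matmul(self.W.value, cols) + self.b.value[None, :, None]
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, self.c_out, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dyf = dy.reshape(n, self.c_out, ho * wo)
        self.W.grad += np.einsum("nop,nkp->ok", dyf, cols, optimize=True)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.W.value.T, dyf).reshape(n, c, k, k, ho, wo)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class Linear(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator | None = None,
                 name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        self.W = Param(f"{name}.W", _he_init(rng, (f_in, f_out), f_in))
        self.b = Param(f"{name}.b", np.zeros(f_out, dtype=DTYPE))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(dy.dtype, copy=False)


class UpsampleNearest2(Layer):
    """Nearest-neighbour x2 upsampling along H and W."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    # stable log(1 + e^x); derivative is sigmoid(x)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def softplus_inverse(y: float) -> float:
    """x such that softplus(x) = y, for y > 0."""
    y = max(float(y), 1e-6)
    return float(y + np.log(-np.expm1(-y))) if y < 20 else float(y)


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3))


def global_avg_pool_backward(dy: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    n, c, h, w = shape
    return np.broadcast_to(dy[:, :, None, None] / (h * w), shape).astype(dy.dtype, copy=False)


class Adam:
    """Adam with bias correction; state keyed by parameter identity order."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
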