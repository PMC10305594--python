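"""Minimal reverse-mode neural-network primitives for volumetric (3D) data.

All operators work on single samples in channels-last layout ``(D, H, W, C)``
(float32); batching is done by the training loop, matching the batch-size-1
protocol used throughout the package.  Convolutions are evaluated as BLAS
matrix products:

* 3x3x3 same-padding convolutions decompose into 27 shifted gemms.  The
  shifted input slab for each kernel offset is copied once into a contiguous
  buffer (channels-last makes that copy cache-friendly) and accumulated
  straight into the output with ``sgemm(beta=1)`` — no temporaries.
* 2x2x2 stride-2 down/up convolutions are non-overlapping and reduce to a
  single reshape + gemm.

Backward passes are exact and every operator is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterator, List, Sequence, Tuple

import numpy as np
from scipy.linalg import blas as _blas

__all__ = [
    "Param",
    "Layer",
    "gemm_acc",
    "pad_spatial",
    "shift_slab",
    "add_shifted",
    "OFFSETS",
    "Conv1x1",
    "DownConv2",
    "UpConv2",
    "GroupNorm",
    "LeakyReLU",
    "Sigmoid",
    "Adam",
    "he_normal",
]

_F32 = np.float32

#: the 27 kernel offsets of a 3x3x3 convolution, in weight-row order
OFFSETS: List[Tuple[int, int, int]] = [
    (a, b, c) for a in range(3) for b in range(3) for c in range(3)
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)

    @property
    def size(self) -> int:
        return self.value.size


def he_normal(rng: np.random.Generator, shape: Sequence[int], fan_in: int,
              slope: float = 0.0) -> np.ndarray:
    """Fan-in scaled normal init (gain adjusted for leaky rectification)."""
    gain = np.sqrt(2.0 / (1.0 + slope ** 2))
    return rng.normal(0.0, gain / np.sqrt(fan_in), size=shape).astype(_F32)


# -- BLAS plumbing ----------------------------------------------------------

def _fortran_op(x: np.ndarray):
    """Express a 2D operand as (F-contiguous array, transpose flag)."""
    if x.flags.f_contiguous:
        return x, 0
    if x.flags.c_contiguous:
        return x.T, 1
    raise ValueError("gemm operand must be C- or F-contiguous")


def gemm_acc(a: np.ndarray, b: np.ndarray, c: np.ndarray,
             alpha: float = 1.0, beta: float = 1.0) -> None:
    """In-place ``c = alpha * (a @ b) + beta * c`` via sgemm, no temporaries.

    ``c`` must be C-contiguous float32; ``a`` and ``b`` C- or F-contiguous.
    """
    # Fortran view: c.T = alpha * b.T @ a.T + beta * c.T
    fa, ta = _fortran_op(b.T)
    fb, tb = _fortran_op(a.T)
    _blas.sgemm(alpha, fa, fb, beta, c.T, trans_a=ta, trans_b=tb,
                overwrite_c=1)


def pad_spatial(x: np.ndarray) -> np.ndarray:
    """Zero-pad the three leading (spatial) axes of a channels-last array."""
    return np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))


def shift_slab(xp: np.ndarray, k: int) -> np.ndarray:
    """Contiguous ``(n_voxels, C)`` view of the padded input shifted by
    kernel offset ``k``."""
    a, b, c = OFFSETS[k]
    d, h, w = xp.shape[0] - 2, xp.shape[1] - 2, xp.shape[2] - 2
    return np.ascontiguousarray(
        xp[a:a + d, b:b + h, c:c + w]).reshape(-1, xp.shape[3])


def add_shifted(dxp: np.ndarray, k: int, piece: np.ndarray) -> None:
    """Scatter-add a ``(n_voxels, C)`` gradient into the padded buffer at
    kernel offset ``k`` (adjoint of :func:`shift_slab`)."""
    a, b, c = OFFSETS[k]
    d, h, w = dxp.shape[0] - 2, dxp.shape[1] - 2, dxp.shape[2] - 2
    dxp[a:a + d, b:b + h, c:c + w] += piece.reshape(d, h, w, -1)


class Layer:
    """Base class: ``forward(x) -> y`` then ``backward(dy) -> dx``."""

    def params(self) -> Iterator[Param]:
        return iter(())

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1x1(Layer):
    """Pointwise channel-mixing convolution (channels-last)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 slope: float = 0.0):
        self.cin, self.cout = cin, cout
        self.w = Param(he_normal(rng, (cin, cout), cin, slope))
        self.b = Param(np.zeros(cout, dtype=_F32))
        self._x2 = None
        self._spatial = None

    def params(self):
        yield self.w
        yield self.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[:-1]
        x2 = x.reshape(-1, self.cin)
        self._x2 = x2
        return (x2 @ self.w.value + self.b.value).reshape(
            self._spatial + (self.cout,))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy2 = dy.reshape(-1, self.cout)
        gemm_acc(self._x2.T, dy2, self.w.grad)
        self.b.grad += dy2.sum(axis=0)
        dx = dy2 @ self.w.value.T
        spatial = self._spatial
        self._x2 = None
        return dx.reshape(spatial + (self.cin,))


def _blockify(x: np.ndarray) -> np.ndarray:
    """(D, H, W, C) -> (D/2 * H/2 * W/2, 8C): gather 2x2x2 blocks."""
    d, h, w, c = x.shape
    xr = x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c)
    return np.ascontiguousarray(
        xr.transpose(0, 2, 4, 1, 3, 5, 6)).reshape(-1, 8 * c)


def _unblockify(x8: np.ndarray, half, c: int) -> np.ndarray:
    d2, h2, w2 = half
    xr = x8.reshape(d2, h2, w2, 2, 2, 2, c).transpose(0, 3, 1, 4, 2, 5, 6)
    return np.ascontiguousarray(xr).reshape(2 * d2, 2 * h2, 2 * w2, c)


class DownConv2(Layer):
    """2x2x2 stride-2 convolution: halves each spatial dim."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 slope: float = 0.0):
        self.cin, self.cout = cin, cout
        self.w = Param(he_normal(rng, (8 * cin, cout), 8 * cin, slope))
        self.b = Param(np.zeros(cout, dtype=_F32))
        self._x8 = None
        self._half = None

    def params(self):
        yield self.w
        yield self.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        d, h, w, _ = x.shape
        if d % 2 or h % 2 or w % 2 or min(d, h, w) < 2:
            raise ValueError(
                f"transition down needs even spatial dims >= 2, got "
                f"{(d, h, w)}")
        self._half = (d // 2, h // 2, w // 2)
        x8 = _blockify(x)
        self._x8 = x8
        return (x8 @ self.w.value + self.b.value).reshape(
            self._half + (self.cout,))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy2 = dy.reshape(-1, self.cout)
        gemm_acc(self._x8.T, dy2, self.w.grad)
        self.b.grad += dy2.sum(axis=0)
        dx8 = dy2 @ self.w.value.T
        self._x8 = None
        return _unblockify(dx8, self._half, self.cin)


class UpConv2(Layer):
    """2x2x2 stride-2 transposed convolution: doubles each spatial dim."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 slope: float = 0.0):
        self.cin, self.cout = cin, cout
        self.w = Param(he_normal(rng, (cin, 8 * cout), cin, slope))
        self.b = Param(np.zeros(cout, dtype=_F32))
        self._x2 = None
        self._spatial = None

    def params(self):
        yield self.w
        yield self.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[:-1]
        x2 = x.reshape(-1, self.cin)
        self._x2 = x2
        y8 = x2 @ self.w.value
        y = _unblockify(y8, self._spatial, self.cout)
        y += self.b.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy8 = _blockify(dy)
        gemm_acc(self._x2.T, dy8, self.w.grad)
        self.b.grad += dy.reshape(-1, self.cout).sum(axis=0)
        dx = dy8 @ self.w.value.T
        spatial = self._spatial
        self._x2 = None
        return dx.reshape(spatial + (self.cin,))


class GroupNorm(Layer):
    """Channel-group normalization, independent of batch size.

    Accepts channels-last ``(..., C)`` input or channels-leading ``(C, n)``
    when ``channels_leading=True`` (the layout used inside fused dense
    blocks).
    """

    def __init__(self, channels: int, groups: int, eps: float = 1e-5,
                 channels_leading: bool = False):
        if channels % groups:
            raise ValueError(
                f"{groups} groups do not divide {channels} channels")
        self.channels, self.groups, self.eps = channels, groups, eps
        self.leading = channels_leading
        self.gamma = Param(np.ones(channels, dtype=_F32))
        self.beta = Param(np.zeros(channels, dtype=_F32))
        self._xhat = None
        self._inv_std = None

    def params(self):
        yield self.gamma
        yield self.beta

    def _grouped(self, x: np.ndarray) -> np.ndarray:
        g = self.groups
        if self.leading:  # (C, n) -> (g, C/g * n)
            return x.reshape(g, -1)
        # (..., C) -> (n, g, C/g) -> (g, n * C/g)
        return np.ascontiguousarray(
            x.reshape(-1, g, self.channels // g).transpose(1, 0, 2)
        ).reshape(g, -1)

    def _ungrouped(self, xg: np.ndarray, shape) -> np.ndarray:
        g = self.groups
        if self.leading:
            return xg.reshape(shape)
        n = int(np.prod(shape[:-1]))
        return np.ascontiguousarray(
            xg.reshape(g, n, self.channels // g).transpose(1, 0, 2)
        ).reshape(shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        xg = self._grouped(x)
        mu = xg.mean(axis=1, keepdims=True)
        var = xg.var(axis=1, keepdims=True)
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        xhat = (xg - mu) * inv_std
        self._xhat, self._inv_std = xhat, inv_std
        y = self._ungrouped(xhat, x.shape)
        if y.base is not None:  # leading mode returns a view of the cache
            y = y.copy()
        if self.leading:
            y *= self.gamma.value[:, None]
            y += self.beta.value[:, None]
        else:
            y *= self.gamma.value
            y += self.beta.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat_full = self._ungrouped(self._xhat, dy.shape)
        if self.leading:
            self.gamma.grad += (dy * xhat_full).sum(axis=1)
            self.beta.grad += dy.sum(axis=1)
            dxhat = dy * self.gamma.value[:, None]
        else:
            axes = tuple(range(dy.ndim - 1))
            self.gamma.grad += (dy * xhat_full).sum(axis=axes)
            self.beta.grad += dy.sum(axis=axes)
            dxhat = dy * self.gamma.value
        dxg = self._grouped(dxhat)
        xhat, inv_std = self._xhat, self._inv_std
        m1 = dxg.mean(axis=1, keepdims=True)
        m2 = (dxg * xhat).mean(axis=1, keepdims=True)
        dx = inv_std * (dxg - m1 - xhat * m2)
        self._xhat = self._inv_std = None
        return self._ungrouped(dx.astype(_F32), dy.shape)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._scale = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        scale = np.where(x < 0, _F32(self.slope), _F32(1.0))
        self._scale = scale
        return x * scale

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._scale
        self._scale = None
        return dx


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        self._y = None
        return dy * y * (1.0 - y)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: List[Param], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
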