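"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This engine provides exactly the operator set the segmentation network
needs: broadcasting arithmetic, elementwise nonlinearities, reductions,
channel concatenation, 3-D convolution (strided, zero-padded),
non-overlapping transposed convolution (kernel == stride) and instance
normalization.  Gradients are accumulated by a topological backward
sweep over the tape recorded during the forward pass.

Convolutions are evaluated by looping over kernel offsets and reducing
each shifted view with an einsum, which keeps peak memory at one input
copy and is fast enough for the patch sizes this package trains on.
"""

from __future__ import annotations

import contextlib
from itertools import product as _product
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit as _expit

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv3d",
    "conv_transpose3d",
    "instance_norm",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nextra = grad.ndim - len(shape)
    if nextra > 0:
        grad = grad.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to our reflected operators instead
    # of NumPy broadcasting the Tensor as a zero-d object
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "f":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents: tuple = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Reverse sweep from this (typically scalar) tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    order.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (g * b.data, g * a.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: (g / b.data, -g * a.data / b.data ** 2))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, n: float):
        return _unary(self, self.data ** n,
                      lambda g, x: g * n * x ** (n - 1.0))

    # -- elementwise ------------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return _unary(self, out, lambda g, x, o=out: g * o)

    def log(self):
        return _unary(self, np.log(self.data), lambda g, x: g / x)

    def sigmoid(self):
        out = _expit(self.data)
        return _unary(self, out, lambda g, x, o=out: g * o * (1.0 - o))

    def leaky_relu(self, slope: float = 0.01):
        out = np.where(self.data >= 0, self.data, slope * self.data)
        return _unary(self, out,
                      lambda g, x: g * np.where(x >= 0, 1.0, slope))

    def clip(self, lo: float, hi: float):
        out = np.clip(self.data, lo, hi)
        return _unary(self, out,
                      lambda g, x: g * ((x > lo) & (x < hi)))

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, x, axis=axis, keepdims=keepdims):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, x.shape)

        return _unary(self, out, bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        orig = self.shape
        return _unary(self, self.data.reshape(*shape),
                      lambda g, x: g.reshape(orig))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unary(a: Tensor, data, grad_fn) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(np.asarray(grad_fn(g, a.data)), a.shape))

    return _make(data, (a,), backward)


def _binary(a, b, fwd, grad_fn) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        ga, gb = grad_fn(g, a, b)
        if a.requires_grad:
            a._accumulate(_unbroadcast(np.asarray(ga), a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.asarray(gb), b.shape))

    return _make(fwd(a.data, b.data), (a, b), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    data = np.concatenate([t.data for t in ts], axis=axis)

    def backward(g):
        offset = 0
        for t, s in zip(ts, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(offset, offset + s)
                t._accumulate(g[tuple(idx)])
            offset += s

    return _make(data, ts, backward)


# -- convolution ----------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: Sequence[int], padding: Sequence[int]) -> Tensor:
    """Strided zero-padded cross-correlation.

    x: (N, C, D, H, W); w: (O, C, kd, kh, kw); b: (O,) or None.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    N, C, D, H, W = x.shape
    O, Cw, kd, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"conv3d: input has {C} channels, weight expects {Cw}")
    sd, sh, sw = stride
    pd, ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    Do = (D + 2 * pd - kd) // sd + 1
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    out = np.zeros((N, O, Do, Ho, Wo), dtype=x.data.dtype)
    for ix, iy, iz in _product(range(kd), range(kh), range(kw)):
        xs = xp[:, :, ix:ix + sd * Do:sd, iy:iy + sh * Ho:sh, iz:iz + sw * Wo:sw]
        out += np.einsum("ncdhw,oc->nodhw", xs, w.data[:, :, ix, iy, iz],
                         optimize=True)
    if b is not None:
        out += _as_tensor(b).data.reshape(1, O, 1, 1, 1)

    parents = [x, w] + ([b] if b is not None else [])

    def backward(g):
        if w.requires_grad:
            gw = np.zeros_like(w.data)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
        for ix, iy, iz in _product(range(kd), range(kh), range(kw)):
            xs = xp[:, :, ix:ix + sd * Do:sd, iy:iy + sh * Ho:sh,
                    iz:iz + sw * Wo:sw]
            if w.requires_grad:
                gw[:, :, ix, iy, iz] = np.einsum("nodhw,ncdhw->oc", g, xs,
                                                 optimize=True)
            if x.requires_grad:
                gxp[:, :, ix:ix + sd * Do:sd, iy:iy + sh * Ho:sh,
                    iz:iz + sw * Wo:sw] += np.einsum(
                        "nodhw,oc->ncdhw", g, w.data[:, :, ix, iy, iz],
                        optimize=True)
        if w.requires_grad:
            w._accumulate(gw)
        if x.requires_grad:
            x._accumulate(gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W])
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    return _make(out, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None,
                     stride: Sequence[int]) -> Tensor:
    """Transposed convolution with kernel == stride (non-overlapping tiles).

    x: (N, C, D, H, W); w: (C, O, kd, kh, kw); output (N, O, D*kd, H*kh, W*kw).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    N, C, D, H, W = x.shape
    Cw, O, kd, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"conv_transpose3d: input has {C} channels, weight expects {Cw}")
    if tuple(stride) != (kd, kh, kw):
        raise ValueError("conv_transpose3d requires kernel == stride")
    out = np.einsum("ncdhw,coxyz->nodxhywz", x.data, w.data, optimize=True)
    out = out.reshape(N, O, D * kd, H * kh, W * kw).copy()
    if b is not None:
        out += _as_tensor(b).data.reshape(1, O, 1, 1, 1)

    parents = [x, w] + ([b] if b is not None else [])

    def backward(g):
        gr = g.reshape(N, O, D, kd, H, kh, W, kw)
        if x.requires_grad:
            x._accumulate(np.einsum("nodxhywz,coxyz->ncdhw", gr, w.data,
                                    optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("ncdhw,nodxhywz->coxyz", x.data, gr,
                                    optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    return _make(out, parents, backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization with affine parameters.

    x: (N, C, *spatial); gamma, beta: (C,).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = tuple(range(2, x.ndim))
    cshape = (1, x.shape[1]) + (1,) * len(axes)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data.reshape(cshape) + beta.data.reshape(cshape)

    def backward(g):
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(cshape)
            gx = inv * (gxhat
                        - gxhat.mean(axis=axes, keepdims=True)
                        - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True))
            x._accumulate(gx)
        red = (0,) + axes
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=red))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=red))

    return _make(out, (x, gamma, beta), backward)
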