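"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps a float32
numpy array, records the operation that produced it, and ``backward()``
walks the tape in reverse topological order.  Only the primitives needed
by a convolutional detector are provided (elementwise arithmetic with
broadcasting, reductions, sigmoid/exp/log/erf/softplus/arctan, slicing,
concatenation, 2-D convolution with groups, batch norm, max pooling and
nearest-neighbour upsampling).

Gradients are accumulated into ``Tensor.grad`` as plain numpy arrays.
A module-level switch (:func:`no_grad`) disables tape construction for
inference so forward passes carry no bookkeeping cost.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "where_positive",
    "conv2d",
    "batch_norm",
    "max_pool2d",
    "upsample_nearest2x",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an autodiff tape behind it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction of tape nodes ------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = (lambda: backward(out)) if backward else None
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # Fresh arrays produced inside backward closures are adopted
        # without a copy; views are materialised.  A closure that passes
        # through ``out.grad`` itself must alias it at most once (see
        # ``__add__``) — after a node's backward has run its gradient is
        # never read again, so single aliasing is safe.
        if self.grad is None:
            if grad.dtype == np.float32 and grad.base is None \
                    and grad.flags.owndata:
                self.grad = grad
            else:
                self.grad = np.array(grad, dtype=np.float32)
        else:
            self.grad += grad

    # -- basic properties ----------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(out):
            aliased = False
            for t in (a, b):
                if t.requires_grad:
                    g = _unbroadcast(out.grad, t.shape)
                    if g is out.grad:
                        if aliased:
                            g = g.copy()
                        aliased = True
                    t._accum(g)

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(out):
            a._accum(-out.grad)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(out):
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(out):
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-out.grad * a.data / (b.data ** 2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        a = self

        def bw(out):
            a._accum(out.grad * p * a.data ** (p - 1))

        return Tensor._make(a.data ** p, (a,), bw)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(out):
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_reduce(self, axis: int, keepdims: bool = False):
        """Max over one axis, gradient routed to the (first) argmax."""
        a = self
        idx = np.argmax(a.data, axis=axis)
        data = np.max(a.data, axis=axis, keepdims=keepdims)

        def bw(out):
            g = out.grad if keepdims else np.expand_dims(out.grad, axis)
            grad = np.zeros_like(a.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), g, axis=axis)
            a._accum(grad)

        return Tensor._make(data, (a,), bw)

    # -- elementwise functions ------------------------------------------
    def sigmoid(self):
        a = self
        y = _sp.expit(a.data)

        def bw(out):
            a._accum(out.grad * y * (1.0 - y))

        return Tensor._make(y, (a,), bw)

    def exp(self):
        a = self
        y = np.exp(a.data)

        def bw(out):
            a._accum(out.grad * y)

        return Tensor._make(y, (a,), bw)

    def log(self):
        a = self

        def bw(out):
            a._accum(out.grad / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        y = np.sqrt(a.data)

        def bw(out):
            a._accum(out.grad * 0.5 / y)

        return Tensor._make(y, (a,), bw)

    def erf(self):
        a = self

        def bw(out):
            a._accum(out.grad * (2.0 / np.sqrt(np.pi)) * np.exp(-a.data ** 2))

        return Tensor._make(_sp.erf(a.data).astype(np.float32), (a,), bw)

    def silu_(self):
        """Fused Swish-1 / SiLU: x * sigmoid(x)."""
        a = self
        sig = _sp.expit(a.data)

        def bw(out):
            a._accum(out.grad * (sig * (1.0 + a.data * (1.0 - sig))))

        return Tensor._make(a.data * sig, (a,), bw)

    def gelu_(self):
        """Fused exact GELU: x * Phi(x), with Phi the standard normal CDF."""
        a = self
        phi = 0.5 * (1.0 + _sp.erf(a.data * np.float32(1 / np.sqrt(2))))

        def bw(out):
            pdf = np.exp(-0.5 * a.data ** 2) * np.float32(1 / np.sqrt(2 * np.pi))
            a._accum(out.grad * (phi + a.data * pdf))

        return Tensor._make((a.data * phi).astype(np.float32), (a,), bw)

    def softplus(self):
        """log(1 + exp(x)), numerically stable."""
        a = self

        def bw(out):
            a._accum(out.grad * _sp.expit(a.data))

        return Tensor._make(np.logaddexp(0.0, a.data).astype(np.float32), (a,), bw)

    def arctan(self):
        a = self

        def bw(out):
            a._accum(out.grad / (1.0 + a.data ** 2))

        return Tensor._make(np.arctan(a.data), (a,), bw)

    def maximum(self, other):
        a, b = self, Tensor._coerce(other)
        mask = a.data >= b.data

        def bw(out):
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * mask, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * (~mask), b.shape))

        return Tensor._make(np.maximum(a.data, b.data), (a, b), bw)

    def minimum(self, other):
        a, b = self, Tensor._coerce(other)
        mask = a.data <= b.data

        def bw(out):
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * mask, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * (~mask), b.shape))

        return Tensor._make(np.minimum(a.data, b.data), (a, b), bw)

    def clamp(self, lo=None, hi=None):
        out = self
        if lo is not None:
            out = out.maximum(lo)
        if hi is not None:
            out = out.minimum(hi)
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(out):
            a._accum(out.grad.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(out):
            a._accum(out.grad.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(out):
            grad = np.zeros(a.shape, dtype=np.float32)
            np.add.at(grad, idx, out.grad)
            a._accum(grad)

        return Tensor._make(a.data[idx], (a,), bw)

    # -- backward pass ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float32))
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # break the tape's reference cycles (closure <-> tensor) so the
        # graph is freed by refcounting instead of gc pauses
        for node in topo:
            node._backward = None
            node._prev = ()


# -- free functions -----------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    sizes = [t.shape[axis] for t in ts]
    offs = np.cumsum([0] + sizes)

    def bw(out):
        sl = [slice(None)] * out.grad.ndim
        for t, o, s in zip(ts, offs, sizes):
            if t.requires_grad:
                sl[axis] = slice(int(o), int(o + s))
                t._accum(out.grad[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, bw)


def where_positive(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select ``a`` where boolean ``cond`` holds, else ``b`` (cond is constant)."""
    a, b = Tensor._coerce(a), Tensor._coerce(b)
    mask = np.asarray(cond, bool)

    def bw(out):
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad * mask, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad * (~mask), b.shape))

    return Tensor._make(np.where(mask, a.data, b.data), (a, b), bw)


# -- convolution and friends --------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            oh: int, ow: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N,C,kh,kw,oh,ow) view-copies per kernel offset."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw]
    return cols

def _col2im(cols: np.ndarray, xshape: tuple, kh: int, kw: int, sh: int, sw: int,
            ph: int, pw: int, oh: int, ow: int) -> np.ndarray:
    n, c, h, w = xshape
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += cols[:, :, i, j]
    return xp[:, :, ph:ph + h, pw:pw + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding, groups.

    Three execution paths: dense convolutions go through im2col + BLAS
    matmul; depthwise convolutions accumulate directly over the k*k
    kernel offsets (no im2col buffer); other group counts fall back to a
    per-group matmul loop.
    """
    n, c, h, wd = x.shape
    cout, cing, kh, kw = w.shape
    if c != cing * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {c}, weight expects {cing * groups}")
    s, p = stride, padding
    oh = (h + 2 * p - kh) // s + 1
    ow = (wd + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    depthwise = groups == c and cing == 1 and cout == c
    parents = (x, w) if b is None else (x, w, b)

    if depthwise:
        out = np.zeros((n, c, oh, ow), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                out += (w.data[:, 0, i, j][None, :, None, None]
                        * xp[:, :, i:i + s * oh:s, j:j + s * ow:s])
        if b is not None:
            out += b.data.reshape(1, cout, 1, 1)

        def bw(o):
            g = o.grad
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.empty_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        gw[:, 0, i, j] = (
                            g * xp[:, :, i:i + s * oh:s, j:j + s * ow:s]
                        ).sum(axis=(0, 2, 3))
                w._accum(gw)
            if x.requires_grad:
                gxp = np.zeros((n, c, h + 2 * p, wd + 2 * p), dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                            w.data[:, 0, i, j][None, :, None, None] * g
                x._accum(gxp[:, :, p:p + h, p:p + wd] if p else gxp)

        return Tensor._make(out, parents, bw)

    cols = _im2col(xp, kh, kw, s, s, oh, ow)
    if groups == 1:
        colm = cols.reshape(n, c * kh * kw, oh * ow)
        w2d = w.data.reshape(cout, c * kh * kw)
        out = np.matmul(w2d[None], colm).reshape(n, cout, oh, ow)
    else:
        colm = cols.reshape(n, groups, cing * kh * kw, oh * ow)
        wg = w.data.reshape(groups, cout // groups, cing * kh * kw)
        out = np.empty((n, groups, cout // groups, oh * ow), dtype=np.float32)
        for gi in range(groups):
            np.matmul(wg[gi][None], colm[:, gi], out=out[:, gi])
        out = out.reshape(n, cout, oh, ow)
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1)

    def bw(o):
        g = o.grad
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            g2 = g.reshape(n, cout, oh * ow)
            if w.requires_grad:
                gw = np.einsum("nop,nkp->ok", g2, colm, optimize=True)
                w._accum(gw.reshape(w.shape))
            if x.requires_grad:
                w2d = w.data.reshape(cout, c * kh * kw)
                gcol = np.matmul(w2d.T[None], g2)
                gcol = gcol.reshape(n, c, kh, kw, oh, ow)
                x._accum(_col2im(gcol, x.shape, kh, kw, s, s, p, p, oh, ow))
        else:
            g2 = g.reshape(n, groups, cout // groups, oh * ow)
            wg2 = w.data.reshape(groups, cout // groups, cing * kh * kw)
            if w.requires_grad:
                gw = np.einsum("ngop,ngkp->gok", g2, colm, optimize=True)
                w._accum(gw.reshape(w.shape))
            if x.requires_grad:
                gcol = np.empty_like(colm)
                for gi in range(groups):
                    np.matmul(wg2[gi].T[None], g2[:, gi], out=gcol[:, gi])
                gcol = gcol.reshape(n, c, kh, kw, oh, ow)
                x._accum(_col2im(gcol, x.shape, kh, kw, s, s, p, p, oh, ow))

    return Tensor._make(out, parents, bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.03,
               eps: float = 1e-3) -> Tensor:
    """Batch normalisation over (N,H,W) per channel; updates running stats
    in place.  The forward pass is a single fused affine ``x*scale+shift``;
    the backward pass uses the closed-form batch-statistics gradient."""
    n, c, h, w = x.shape
    m = n * h * w
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    invstd = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    mu = mu.astype(np.float32)
    scale = gamma.data * invstd
    shift = beta.data - mu * scale
    out = x.data * scale.reshape(1, c, 1, 1) + shift.reshape(1, c, 1, 1)

    def bw(o):
        g = o.grad
        gsum = g.sum(axis=(0, 2, 3))
        if beta.requires_grad:
            beta._accum(gsum.astype(np.float32))
        xhat = (x.data - mu.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)
        gxsum = (g * xhat).sum(axis=(0, 2, 3))
        if gamma.requires_grad:
            gamma._accum(gxsum.astype(np.float32))
        if x.requires_grad:
            if training:
                # gx = scale * (g - gsum/m - xhat * gxsum/m)
                xhat *= (-gxsum / m).reshape(1, c, 1, 1)
                xhat += g
                xhat -= (gsum / m).reshape(1, c, 1, 1)
                xhat *= scale.reshape(1, c, 1, 1)
                x._accum(xhat)
            else:
                x._accum(g * scale.reshape(1, c, 1, 1))

    return Tensor._make(out, (x, gamma, beta), bw)


def max_pool2d(x: Tensor, kernel: int, stride: int = 1,
               padding: int | None = None) -> Tensor:
    """Max pooling with 'same'-style default padding (as used by SPP).

    The backward pass routes the gradient to every window element equal
    to the window maximum (exact ties share the gradient, a measure-zero
    event for continuous activations).
    """
    if padding is None:
        padding = kernel // 2
    n, c, h, w = x.shape
    s, p, k = stride, padding, kernel
    oh = (h + 2 * p - k) // s + 1
    ow = (w + 2 * p - k) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf) if p else x.data
    out = np.full((n, c, oh, ow), -np.inf, dtype=np.float32)
    for i in range(k):
        for j in range(k):
            np.maximum(out, xp[:, :, i:i + s * oh:s, j:j + s * ow:s], out=out)

    def bw(o):
        xg = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                win = xp[:, :, i:i + s * oh:s, j:j + s * ow:s]
                xg[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                    o.grad * (win == out)
        x._accum(xg[:, :, p:p + h, p:p + w] if p else xg)

    return Tensor._make(out, (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape

    def bw(o):
        x._accum(o.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), (x,), bw)
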