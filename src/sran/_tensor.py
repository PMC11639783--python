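"""Minimal reverse-mode automatic differentiation over numpy arrays.

All tensors are float64 and image tensors use NHWC layout (batch, height,
width, channels).  The engine is tape-free: each operation closes over its
inputs and contributes a backward function; ``Tensor.backward`` walks the
graph in reverse topological order.  Only the operations needed by the
embedding network are provided (broadcast arithmetic, matmul, 2-D
convolution via im2col, reductions with max routing, sigmoid/softplus/relu,
concatenation and reshape).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- convenience -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self):
        return float(self.data)

    # -- graph traversal -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if p.requires_grad and id(p) not in seen:
                        stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_t(other), -1.0))

    def __rsub__(self, other):
        return add(_t(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(_t(other), -1.0))

    def __pow__(self, e):
        return power(self, e)


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- arithmetic ----------------------------------------------------------
def add(a, b) -> Tensor:
    a, b = _t(a), _t(b)

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(a.data + b.data, parents=(a, b), backward=bw)


def mul(a, b) -> Tensor:
    a, b = _t(a), _t(b)

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(a.data * b.data, parents=(a, b), backward=bw)


def power(a, e: float) -> Tensor:
    a = _t(a)
    e = float(e)
    out_data = a.data ** e

    def bw(g):
        _accum(a, g * e * a.data ** (e - 1.0))

    return Tensor(out_data, parents=(a,), backward=bw)


def sqrt(a) -> Tensor:
    a = _t(a)
    root = np.sqrt(a.data)

    def bw(g):
        _accum(a, g * 0.5 / root)

    return Tensor(root, parents=(a,), backward=bw)


def matmul(a, b) -> Tensor:
    a, b = _t(a), _t(b)

    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return Tensor(a.data @ b.data, parents=(a, b), backward=bw)


# -- reductions ----------------------------------------------------------
def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = _t(a)

    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        gk = g if keepdims else np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(gk, a.data.shape).copy())

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,), backward=bw)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = _t(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))

    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g / n, a.data.shape).copy())
            return
        gk = g if keepdims else np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(gk / n, a.data.shape).copy())

    return Tensor(a.data.mean(axis=axis, keepdims=keepdims), parents=(a,), backward=bw)


def reduce_max(a, axis, keepdims=False) -> Tensor:
    """Max over ``axis``; ties share the incoming gradient equally."""
    a = _t(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)
    kept = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == kept).astype(np.float64)
    mask /= mask.sum(axis=axis, keepdims=True)

    def bw(g):
        gk = g if keepdims else np.expand_dims(g, axis)
        _accum(a, mask * gk)

    return Tensor(out_data, parents=(a,), backward=bw)


# -- shape ops -----------------------------------------------------------
def reshape(a, shape) -> Tensor:
    a = _t(a)

    def bw(g):
        _accum(a, g.reshape(a.data.shape))

    return Tensor(a.data.reshape(shape), parents=(a,), backward=bw)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_t(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bw,
    )


# -- activations ---------------------------------------------------------
def relu(a) -> Tensor:
    a = _t(a)
    mask = a.data > 0

    def bw(g):
        _accum(a, g * mask)

    return Tensor(a.data * mask, parents=(a,), backward=bw)


def sigmoid(a) -> Tensor:
    a = _t(a)
    s = expit(a.data)

    def bw(g):
        _accum(a, g * s * (1.0 - s))

    return Tensor(s, parents=(a,), backward=bw)


def softplus(a) -> Tensor:
    a = _t(a)

    def bw(g):
        _accum(a, g * expit(a.data))

    return Tensor(np.logaddexp(0.0, a.data), parents=(a,), backward=bw)


def clamp_min(a, lo: float) -> Tensor:
    a = _t(a)
    mask = a.data >= lo

    def bw(g):
        _accum(a, g * mask)

    return Tensor(np.maximum(a.data, lo), parents=(a,), backward=bw)


# -- convolution and pooling ---------------------------------------------
def _same_pads(size, kernel, stride):
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


def _im2col(xp, kh, kw, stride):
    # xp: padded (N, Hp, Wp, C) -> cols (N, Ho, Wo, kh, kw, C)
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (N, Ho, Wo, C, kh, kw)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))


def conv2d(x, w, b=None, stride=1, padding="same") -> Tensor:
    """2-D convolution, NHWC input, (kh, kw, c_in, f) kernel, SAME/VALID pad."""
    x, w = _t(x), _t(w)
    if b is not None:
        b = _t(b)
    n, h, wd, c = x.data.shape
    kh, kw, cin, f = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d: input has {c} channels, kernel built for {cin}")
    if padding == "same":
        pt, pb = _same_pads(h, kh, stride)
        pl, pr = _same_pads(wd, kw, stride)
    elif padding == "valid":
        pt = pb = pl = pr = 0
    else:  # pragma: no cover
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    cols = _im2col(xp, kh, kw, stride)  # (N, Ho, Wo, kh, kw, C)
    n_, ho, wo = cols.shape[:3]
    cols2 = cols.reshape(n_ * ho * wo, kh * kw * c)
    wmat = w.data.reshape(kh * kw * c, f)
    out_data = (cols2 @ wmat).reshape(n_, ho, wo, f)
    if b is not None:
        out_data = out_data + b.data

    def bw(g):
        gflat = g.reshape(n_ * ho * wo, f)
        if w.requires_grad:
            _accum(w, (cols2.T @ gflat).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            dcols = (gflat @ wmat.T).reshape(n_, ho, wo, kh, kw, c)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + ho * stride : stride, j : j + wo * stride : stride] += dcols[:, :, :, i, j]
            _accum(x, dxp[:, pt : pt + h, pl : pl + wd])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bw)


def maxpool2d(x, pool=3, stride=2) -> Tensor:
    """Spatial max pooling with SAME padding (ties share the gradient)."""
    x = _t(x)
    n, h, wd, c = x.data.shape
    pt, pb = _same_pads(h, pool, stride)
    pl, pr = _same_pads(wd, pool, stride)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=-np.inf)
    win = sliding_window_view(xp, (pool, pool), axis=(1, 2))[:, ::stride, ::stride]
    out_data = win.max(axis=(4, 5))  # (N, Ho, Wo, C)
    ho, wo = out_data.shape[1:3]

    def bw(g):
        if not x.requires_grad:
            return
        mask = win == out_data[..., None, None]
        mask = mask / mask.sum(axis=(4, 5), keepdims=True)
        contrib = mask * g[..., None, None]  # (N, Ho, Wo, C, p, p)
        dxp = np.zeros_like(xp)
        for i in range(pool):
            for j in range(pool):
                dxp[:, i : i + ho * stride : stride, j : j + wo * stride : stride] += contrib[..., i, j]
        _accum(x, dxp[:, pt : pt + h, pl : pl + wd])

    return Tensor(out_data, parents=(x,), backward=bw)
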