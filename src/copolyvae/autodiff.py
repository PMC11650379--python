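"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-free, graph-based autodiff: every operation returns a :class:`Tensor`
holding the forward value, references to its parents and a closure that
propagates the upstream gradient.  Only the operations needed by the VAE
(dense algebra, attention, softmax cross-entropy) are implemented, all fully
vectorised.  Functions in this module accept plain ``numpy`` arrays as well,
in which case they compute forward-only with no graph, so the same model code
serves both training and inference.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32  # training dtype; inference paths may use float64 arrays

__all__ = [
    "Tensor", "matmul", "exp", "log", "tanh", "relu", "sigmoid", "sqrt",
    "tsum", "tmean", "reshape", "transpose", "concatenate", "take",
    "log_softmax", "softmax", "swapaxes", "broadcast_to", "where_mask",
    "attention", "cross_entropy_logits",
]


def _as_array(x):
    if isinstance(x, Tensor):
        return x.data
    return x if isinstance(x, np.ndarray) else np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        d = np.asarray(data)
        self.data = d if d.dtype == DTYPE else d.astype(DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not isinstance(t, Tensor):
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=DTYPE)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        # accumulation is never in-place, so sharing the first array is safe
        self.grad = g if self.grad is None else self.grad + g

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return _binop(self, other, np.add,
                      lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binop(self, other, np.subtract,
                      lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _binop(other, self, np.subtract,
                      lambda g, a, b: (g, -g))

    def __mul__(self, other):
        return _binop(self, other, np.multiply,
                      lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binop(self, other, np.divide,
                      lambda g, a, b: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return _binop(other, self, np.divide,
                      lambda g, a, b: (g / b, -g * a / (b * b)))

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p: float):
        a = self.data
        out = Tensor(a ** p, requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            self._accum(g * p * a ** (p - 1))
        out._backward = bw if self.requires_grad else None
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        out = Tensor(out_data, requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bw if self.requires_grad else None
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _needs_graph(*xs) -> bool:
    return any(isinstance(x, Tensor) and x.requires_grad for x in xs)


def _binop(a, b, fwd, grads):
    a_t, b_t = a if isinstance(a, Tensor) else None, b if isinstance(b, Tensor) else None
    ad, bd = _as_array(a), _as_array(b)
    if not _needs_graph(a, b):
        res = fwd(ad, bd)
        return Tensor(res) if (a_t is not None or b_t is not None) else res
    out = Tensor(fwd(ad, bd), requires_grad=True,
                 parents=tuple(t for t in (a_t, b_t) if t is not None))

    def bw(g):
        ga, gb = grads(g, ad, bd)
        if a_t is not None and a_t.requires_grad:
            a_t._accum(_unbroadcast(ga, ad.shape))
        if b_t is not None and b_t.requires_grad:
            b_t._accum(_unbroadcast(gb, bd.shape))
    out._backward = bw
    return out


# -- functional ops ---------------------------------------------------------

def matmul(a, b):
    ad, bd = _as_array(a), _as_array(b)
    if not _needs_graph(a, b):
        res = ad @ bd
        return Tensor(res) if isinstance(a, Tensor) or isinstance(b, Tensor) else res
    a_t = a if isinstance(a, Tensor) else None
    b_t = b if isinstance(b, Tensor) else None
    out = Tensor(ad @ bd, requires_grad=True,
                 parents=tuple(t for t in (a_t, b_t) if t is not None))

    def bw(g):
        if a_t is not None and a_t.requires_grad:
            ga = g @ np.swapaxes(bd, -1, -2)
            a_t._accum(_unbroadcast(ga, ad.shape))
        if b_t is not None and b_t.requires_grad:
            gb = np.swapaxes(ad, -1, -2) @ g
            b_t._accum(_unbroadcast(gb, bd.shape))
    out._backward = bw
    return out


def _unary(x, fwd, grad_fn):
    xd = _as_array(x)
    yd = fwd(xd)
    if not _needs_graph(x):
        return Tensor(yd) if isinstance(x, Tensor) else yd
    out = Tensor(yd, requires_grad=True, parents=(x,))

    def bw(g):
        x._accum(g * grad_fn(xd, yd))
    out._backward = bw
    return out


def exp(x):
    return _unary(x, np.exp, lambda xd, yd: yd)


def log(x):
    return _unary(x, np.log, lambda xd, yd: 1.0 / xd)


def sqrt(x):
    return _unary(x, np.sqrt, lambda xd, yd: 0.5 / yd)


def tanh(x):
    return _unary(x, np.tanh, lambda xd, yd: 1.0 - yd * yd)


def relu(x):
    return _unary(x, lambda a: np.maximum(a, 0.0), lambda xd, yd: (xd > 0).astype(xd.dtype))


def sigmoid(x):
    return _unary(x, lambda a: 1.0 / (1.0 + np.exp(-a)), lambda xd, yd: yd * (1.0 - yd))


def tsum(x, axis=None, keepdims=False):
    xd = _as_array(x)
    yd = xd.sum(axis=axis, keepdims=keepdims)
    if not _needs_graph(x):
        return Tensor(yd) if isinstance(x, Tensor) else yd
    out = Tensor(yd, requires_grad=True, parents=(x,))

    def bw(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(np.broadcast_to(g, xd.shape).copy())
    out._backward = bw
    return out


def tmean(x, axis=None, keepdims=False):
    xd = _as_array(x)
    n = xd.size if axis is None else xd.shape[axis]
    return tsum(x, axis=axis, keepdims=keepdims) / float(n)


def reshape(x, shape):
    xd = _as_array(x)
    yd = xd.reshape(shape)
    if not _needs_graph(x):
        return Tensor(yd) if isinstance(x, Tensor) else yd
    out = Tensor(yd, requires_grad=True, parents=(x,))

    def bw(g):
        x._accum(np.asarray(g).reshape(xd.shape))
    out._backward = bw
    return out


def transpose(x, axes):
    xd = _as_array(x)
    yd = xd.transpose(axes)
    if not _needs_graph(x):
        return Tensor(yd) if isinstance(x, Tensor) else yd
    out = Tensor(yd, requires_grad=True, parents=(x,))
    inv = np.argsort(axes)

    def bw(g):
        x._accum(np.asarray(g).transpose(inv))
    out._backward = bw
    return out


def swapaxes(x, a, b):
    nd = _as_array(x).ndim
    axes = list(range(nd))
    axes[a], axes[b] = axes[b], axes[a]
    return transpose(x, axes)


def concatenate(xs, axis=0):
    datas = [_as_array(x) for x in xs]
    yd = np.concatenate(datas, axis=axis)
    if not any(_needs_graph(x) for x in xs):
        return Tensor(yd) if any(isinstance(x, Tensor) for x in xs) else yd
    parents = tuple(x for x in xs if isinstance(x, Tensor))
    out = Tensor(yd, requires_grad=True, parents=parents)
    sizes = [d.shape[axis] for d in datas]

    def bw(g):
        g = np.asarray(g)
        offs = np.cumsum([0] + sizes)
        sl = [slice(None)] * g.ndim
        for x, lo, hi in zip(xs, offs[:-1], offs[1:]):
            if isinstance(x, Tensor) and x.requires_grad:
                sl[axis] = slice(lo, hi)
                x._accum(g[tuple(sl)])
    out._backward = bw
    return out


def take(x, idx):
    """Row gather (embedding lookup): out[...] = x[idx, :]."""
    xd = _as_array(x)
    idx = np.asarray(idx)
    yd = xd[idx]
    if not _needs_graph(x):
        return Tensor(yd) if isinstance(x, Tensor) else yd
    out = Tensor(yd, requires_grad=True, parents=(x,))

    def bw(g):
        full = np.zeros_like(xd)
        np.add.at(full, idx.reshape(-1), np.asarray(g).reshape(-1, xd.shape[-1]))
        x._accum(full)
    out._backward = bw
    return out


def log_softmax(x, axis=-1):
    """Numerically stable fused log-softmax with analytic backward."""
    xd = _as_array(x)
    m = xd.max(axis=axis, keepdims=True)
    s = xd - m
    lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
    yd = s - lse
    if not _needs_graph(x):
        return Tensor(yd) if isinstance(x, Tensor) else yd
    out = Tensor(yd, requires_grad=True, parents=(x,))

    def bw(g):
        g = np.asarray(g)
        sm = np.exp(yd)
        x._accum(g - sm * g.sum(axis=axis, keepdims=True))
    out._backward = bw
    return out


def softmax(x, axis=-1):
    """Fused softmax with analytic backward (dx = y*(g - sum(g*y)))."""
    xd = _as_array(x)
    e = np.exp(xd - xd.max(axis=axis, keepdims=True))
    yd = e / e.sum(axis=axis, keepdims=True)
    if not _needs_graph(x):
        return Tensor(yd) if isinstance(x, Tensor) else yd
    out = Tensor(yd, requires_grad=True, parents=(x,))

    def bw(g):
        g = np.asarray(g)
        x._accum(yd * (g - (g * yd).sum(axis=axis, keepdims=True)))
    out._backward = bw
    return out


def attention(q, k, v, bias=None, scale: float = 1.0):
    """Fused scaled-dot-product attention: softmax(scale*q@k^T + bias) @ v.

    q, k, v: (..., Lq, dh), (..., Lk, dh), (..., Lk, dh); bias broadcasts to
    (..., Lq, Lk).  Single graph node with analytic backward, which keeps the
    large (Lq, Lk) intermediates out of the autodiff graph.
    """
    qd, kd, vd = _as_array(q), _as_array(k), _as_array(v)
    scores = (qd * scale) @ np.swapaxes(kd, -1, -2)
    if bias is not None:
        scores += bias
    scores -= scores.max(axis=-1, keepdims=True)
    np.exp(scores, out=scores)
    scores /= scores.sum(axis=-1, keepdims=True)
    w = scores
    yd = w @ vd
    if not _needs_graph(q, k, v):
        return Tensor(yd) if any(isinstance(t, Tensor) for t in (q, k, v)) else yd
    out = Tensor(yd, requires_grad=True,
                 parents=tuple(t for t in (q, k, v) if isinstance(t, Tensor)))

    def bw(g):
        g = np.asarray(g)
        if isinstance(v, Tensor) and v.requires_grad:
            v._accum(_unbroadcast(np.swapaxes(w, -1, -2) @ g, vd.shape))
        gw = g @ np.swapaxes(vd, -1, -2)
        gs = w * (gw - (gw * w).sum(axis=-1, keepdims=True))
        if isinstance(q, Tensor) and q.requires_grad:
            q._accum(_unbroadcast((gs @ kd) * scale, qd.shape))
        if isinstance(k, Tensor) and k.requires_grad:
            k._accum(_unbroadcast(np.swapaxes(gs, -1, -2) @ (qd * scale), kd.shape))
    out._backward = bw
    return out


def cross_entropy_logits(logits, targets, weights):
    """Weighted mean token cross entropy from raw logits.

    logits: (B, L, V); targets: (B, L) int; weights: (B, L) nonnegative.
    Returns a scalar: sum_w(-log p[target]) / sum(weights).
    """
    xd = _as_array(logits)
    targets = np.asarray(targets)
    weights = np.asarray(weights, dtype=xd.dtype)
    m = xd.max(axis=-1, keepdims=True)
    s = xd - m
    es = np.exp(s)
    z = es.sum(axis=-1, keepdims=True)
    logp_t = np.take_along_axis(s, targets[..., None], axis=-1)[..., 0] - np.log(z[..., 0])
    denom = weights.sum()
    val = -(logp_t * weights).sum() / denom
    if not _needs_graph(logits):
        return Tensor(val) if isinstance(logits, Tensor) else val
    out = Tensor(val, requires_grad=True, parents=(logits,))

    def bw(g):
        g = float(g)
        grad = es / z                                   # softmax probabilities
        bi, li = np.meshgrid(np.arange(xd.shape[0]), np.arange(xd.shape[1]),
                             indexing="ij")
        grad[bi, li, targets] -= 1.0
        grad *= (g / denom) * weights[..., None]
        logits._accum(grad)
    out._backward = bw
    return out


def broadcast_to(x, shape):
    xd = _as_array(x)
    yd = np.broadcast_to(xd, shape)
    if not _needs_graph(x):
        return Tensor(yd.copy()) if isinstance(x, Tensor) else yd.copy()
    out = Tensor(yd.copy(), requires_grad=True, parents=(x,))

    def bw(g):
        x._accum(_unbroadcast(np.asarray(g), xd.shape))
    out._backward = bw
    return out


def where_mask(mask, x):
    """Multiply by a constant 0/1 mask (gradient masked accordingly)."""
    return x * np.asarray(mask, dtype=_as_array(x).dtype)
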