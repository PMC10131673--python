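"""A small reverse-mode autodiff engine on numpy arrays.

This is the numerical substrate of the severity network: tensors carry a
value and, after ``backward()``, a gradient, with the graph built eagerly
by the op functions below.  The op set is deliberately minimal — exactly
what an SE-CNN with an attention branch, max+mean multi-view fusion and
regression/classification heads needs:

* elementwise add / mul / neg with broadcasting, matmul
* relu, sigmoid
* reshape, concat, mean/sum/max reductions
* 2-D convolution (im2col), embedding lookup
* smooth-L1, softmax cross-entropy and binary cross-entropy losses
* ``detach`` for stop-gradients (the teacher side of cross-teacher terms)

Every op's gradient is verified against central finite differences in the
test suite.  All computation is float64 numpy, single process; given the
same inputs it is bit-deterministic.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "add", "mul", "neg", "sub", "matmul", "relu", "sigmoid",
    "reshape", "concat", "mean", "reduce_sum", "reduce_max",
    "conv2d", "embedding",
    "smooth_l1_loss", "softmax_cross_entropy", "bce_with_logits",
    "Adam",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # light operator sugar (constants are wrapped)
    def __add__(self, other):
        return add(self, _wrap(other))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _node(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _needs(*parents):
        out._parents = tuple(parents)
        out._backward = backward(out)
    return out


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            _accum(a, _unbroadcast(out.grad, a.shape))
            _accum(b, _unbroadcast(out.grad, b.shape))
        return run
    return _node(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            _accum(a, _unbroadcast(out.grad * b.data, a.shape))
            _accum(b, _unbroadcast(out.grad * a.data, b.shape))
        return run
    return _node(a.data * b.data, (a, b), bw)


def neg(a: Tensor) -> Tensor:
    def bw(out):
        def run():
            _accum(a, -out.grad)
        return run
    return _node(-a.data, (a,), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, neg(b))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            _accum(a, out.grad @ b.data.T)
            _accum(b, a.data.T @ out.grad)
        return run
    return _node(a.data @ b.data, (a, b), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(out):
        def run():
            _accum(a, out.grad * mask)
        return run
    return _node(a.data * mask, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bw(out):
        def run():
            _accum(a, out.grad * s * (1.0 - s))
        return run
    return _node(s, (a,), bw)


# ---------------------------------------------------------------------------
# shape / reductions
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    def bw(out):
        def run():
            _accum(a, out.grad.reshape(a.shape))
        return run
    return _node(a.data.reshape(shape), (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(out):
        def run():
            for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
                _accum(t, g)
        return run
    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)]
    )

    def bw(out):
        def run():
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, tuple(np.atleast_1d(axis)))
            _accum(a, np.broadcast_to(g, a.shape) / n)
        return run
    return _node(a.data.mean(axis=axis, keepdims=keepdims), (a,), bw)


def reduce_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def bw(out):
        def run():
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, tuple(np.atleast_1d(axis)))
            _accum(a, np.broadcast_to(g, a.shape))
        return run
    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def reduce_max(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; ties split the gradient equally."""
    mx = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == mx).astype(np.float64)
    mask /= mask.sum(axis=axis, keepdims=True)

    def bw(out):
        def run():
            g = out.grad
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, mask * g)
        return run
    return _node(mx if keepdims else mx.squeeze(axis), (a,), bw)


# ---------------------------------------------------------------------------
# convolution / embedding
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (b, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(cols).reshape(b, c * kh * kw, oh * ow), (oh, ow, h, w)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (B,C,H,W); weight: (F,C,kh,kw); bias: (F,) -> (B,F,OH,OW)."""
    f, c, kh, kw = weight.shape
    cols, (oh, ow, ph, pw) = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(f, c * kh * kw)
    out_data = np.einsum("fk,bkp->bfp", wmat, cols).reshape(-1, f, oh, ow)
    out_data += bias.data[None, :, None, None]

    def bw(out):
        def run():
            g = out.grad.reshape(out.grad.shape[0], f, oh * ow)
            _accum(bias, g.sum(axis=(0, 2)))
            gw = np.einsum("bfp,bkp->fk", g, cols).reshape(weight.shape)
            _accum(weight, gw)
            gcols = np.einsum("fk,bfp->bkp", wmat, g)
            gx = _col2im(gcols, x.data.shape, kh, kw, stride, pad, oh, ow)
            _accum(x, gx)
        return run
    return _node(out_data, (x, weight, bias), bw)


def _col2im(gcols, x_shape, kh, kw, stride, pad, oh, ow):
    b, c, h, w = x_shape
    gx = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    gcols = gcols.reshape(b, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += gcols[
                :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup: table (V, D), idx (B,) ints -> (B, D)."""
    idx = np.asarray(idx, dtype=np.intp)

    def bw(out):
        def run():
            if table.grad is None:
                table.grad = np.zeros_like(table.data)
            np.add.at(table.grad, idx, out.grad)
        return run
    return _node(table.data[idx], (table,), bw)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def smooth_l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean smooth-L1: 0.5 d^2 for |d| < 1, |d| - 0.5 beyond."""
    t = np.asarray(target, dtype=np.float64)
    d = pred.data - t
    small = np.abs(d) < 1.0
    vals = np.where(small, 0.5 * d * d, np.abs(d) - 0.5)
    n = d.size

    def bw(out):
        def run():
            _accum(pred, out.grad * np.where(small, d, np.sign(d)) / n)
        return run
    return _node(vals.mean(), (pred,), bw)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax(logits (B,K))."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    b = labels.shape[0]
    nll = -np.log(np.maximum(p[np.arange(b), labels], 1e-300))

    def bw(out):
        def run():
            g = p.copy()
            g[np.arange(b), labels] -= 1.0
            _accum(logits, out.grad * g / b)
        return run
    return _node(nll.mean(), (logits,), bw)


def bce_with_logits(logits: Tensor, target: np.ndarray, sample_weight: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against soft targets.

    ``sample_weight`` (broadcastable 0/1 array) selects which elements are
    supervised; the mean runs over the selected elements only.
    """
    t = np.asarray(target, dtype=np.float64)
    x = logits.data
    s = 1.0 / (1.0 + np.exp(-x))
    # stable: max(x,0) - x*t + log1p(exp(-|x|))
    per = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    if sample_weight is None:
        w = np.ones_like(per)
    else:
        w = np.broadcast_to(np.asarray(sample_weight, dtype=np.float64), per.shape)
    denom = max(w.sum(), 1.0)

    def bw(out):
        def run():
            _accum(logits, out.grad * w * (s - t) / denom)
        return run
    return _node((per * w).sum() / denom, (logits,), bw)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment optimizer over a name -> Parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)
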