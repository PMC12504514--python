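"""Minimal reverse-mode automatic differentiation on numpy arrays.

All model forward passes and composite losses are built from the small set of
differentiable primitives below, so analytic gradients of any scalar objective
with respect to any parameter are available exactly (float64 throughout).
Most helpers dispatch on input type: given plain ndarrays they compute values
only, given :class:`Tensor` they record the graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "value_of",
    "exp",
    "log",
    "tanh",
    "sigmoid",
    "clip",
    "tsum",
    "tmean",
    "stack",
    "concat",
    "softmax_masked",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "_parents", "_bw", "requires_grad")

    # make ndarray <op> Tensor defer to the reflected Tensor methods
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, value, parents=(), bw=None, requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._bw = bw
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    # ---- graph traversal -------------------------------------------------
    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        for n in topo:
            n.grad = np.zeros_like(n.value)
        self.grad = np.ones_like(self.value)
        for n in reversed(topo):
            if n._bw is not None:
                n._bw(n.grad)

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        out = Tensor(self.value + other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.value.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.value.shape)

        out._bw = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += -g

        out._bw = bw
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(self.value * other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.value, self.value.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.value, other.value.shape)

        out._bw = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        out = Tensor(self.value / other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.value, self.value.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.value / other.value**2, other.value.shape
                )

        out._bw = bw
        return out

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.value**p, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * p * self.value ** (p - 1)

        out._bw = bw
        return out

    def __matmul__(self, other):
        other = tensor(other)
        out = Tensor(self.value @ other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ other.value.swapaxes(-1, -2)
                self.grad += _unbroadcast(ga, self.value.shape)
            if other.requires_grad:
                gb = self.value.swapaxes(-1, -2) @ g
                other.grad += _unbroadcast(gb, other.value.shape)

        out._bw = bw
        return out

    @property
    def T(self):
        out = Tensor(self.value.swapaxes(-1, -2), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g.swapaxes(-1, -2)

        out._bw = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.value[idx], (self,))

        def bw(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)

        out._bw = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.value.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(self.value.shape)

        out._bw = bw
        return out


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def value_of(x):
    """Underlying float/ndarray of either a Tensor or plain value."""
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


# ---- elementwise functions (dispatch on type) ------------------------------


def _unary(x, fn, dfn):
    if not isinstance(x, Tensor):
        return fn(np.asarray(x, dtype=np.float64))
    out = Tensor(fn(x.value), (x,))

    def bw(g):
        if x.requires_grad:
            x.grad += g * dfn(x.value, out.value)

    out._bw = bw
    return out


def exp(x):
    return _unary(x, np.exp, lambda v, o: o)


def log(x):
    return _unary(x, np.log, lambda v, o: 1.0 / v)


def tanh(x):
    return _unary(x, np.tanh, lambda v, o: 1.0 - o**2)


def sigmoid(x):
    def f(v):
        return 0.5 * (np.tanh(0.5 * v) + 1.0)  # numerically stable

    return _unary(x, f, lambda v, o: o * (1.0 - o))


def clip(x, lo: float, hi: float):
    """Clamp values; gradient passes through only inside (lo, hi)."""
    if not isinstance(x, Tensor):
        return np.clip(np.asarray(x, dtype=np.float64), lo, hi)
    out = Tensor(np.clip(x.value, lo, hi), (x,))
    inside = (x.value > lo) & (x.value < hi)

    def bw(g):
        if x.requires_grad:
            x.grad += g * inside

    out._bw = bw
    return out


def tsum(x, axis=None, keepdims=False):
    if not isinstance(x, Tensor):
        return np.sum(np.asarray(x, dtype=np.float64), axis=axis, keepdims=keepdims)
    out = Tensor(x.value.sum(axis=axis, keepdims=keepdims), (x,))

    def bw(g):
        if not x.requires_grad:
            return
        if axis is None:
            x.grad += g * np.ones_like(x.value)
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            x.grad += np.broadcast_to(gg, x.value.shape)

    out._bw = bw
    return out


def tmean(x, axis=None):
    n = value_of(x).size if axis is None else value_of(x).shape[axis]
    return tsum(x, axis=axis) / float(n)


def stack(xs, axis=0):
    if not any(isinstance(x, Tensor) for x in xs):
        return np.stack(xs, axis=axis)
    xs = [tensor(x) for x in xs]
    out = Tensor(np.stack([x.value for x in xs], axis=axis), tuple(xs))

    def bw(g):
        for i, x in enumerate(xs):
            if x.requires_grad:
                x.grad += np.take(g, i, axis=axis)

    out._bw = bw
    return out


def concat(xs, axis=0):
    if not any(isinstance(x, Tensor) for x in xs):
        return np.concatenate(xs, axis=axis)
    xs = [tensor(x) for x in xs]
    out = Tensor(np.concatenate([x.value for x in xs], axis=axis), tuple(xs))
    sizes = [x.value.shape[axis] for x in xs]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for i, x in enumerate(xs):
            if x.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offsets[i], offsets[i + 1])
                x.grad += g[tuple(sl)]

    out._bw = bw
    return out


def softmax_masked(scores, mask, axis=-1):
    """Softmax over positions where boolean `mask` is true.

    Masked positions get weight exactly zero; scores are shifted by the
    per-row max for stability. `mask` is a constant ndarray.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=axis).all():
        raise ValueError("softmax over a fully masked axis is undefined")
    v = value_of(scores)
    shift = np.max(np.where(mask, v, -np.inf), axis=axis, keepdims=True)
    z = exp((scores - shift) * mask.astype(float)) * mask.astype(float)
    return z / tsum(z, axis=axis, keepdims=True)
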