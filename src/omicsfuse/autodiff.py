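"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training stack (omics encoders, attention, multi-subspace encoder, the
ZINB/Bernoulli decoders and the mutual-information losses) is expressed once
in terms of the generic functions below, which accept either plain numpy
arrays (returning numpy results) or :class:`Tensor` leaves (returning a
``Tensor`` that supports ``backward()``).  This keeps the value computed by
the public, array-facing API and the value differentiated during training
literally the same code path.

Only the operations this package needs are implemented; gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor",
    "Adam",
    "exp",
    "log",
    "log1p",
    "sqrt",
    "softplus",
    "sigmoid",
    "lgamma",
    "relu",
    "elu",
    "softmax_rows",
    "logaddexp",
    "where",
    "clip",
    "concat_cols",
    "take_rows",
    "matmul",
    "summ",
    "mean",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")
    __array_priority__ = 100  # ensure ndarray.__op__ defers to Tensor

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)
        self.name = name

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self):
        out = Tensor(self.data.T, self.requires_grad, (self,))

        def bw(g):
            return (g.T,)

        out._backward = bw
        return out

    def detach(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._prev))]
        seen.add(id(self))
        while stack:
            node, it = stack[-1]
            nxt = next(it, None)
            if nxt is None:
                topo.append(node)
                stack.pop()
            elif id(nxt) not in seen:
                seen.add(id(nxt))
                stack.append((nxt, iter(nxt._prev)))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._prev, grads):
                if g is not None and (parent.requires_grad or parent._prev):
                    parent._accum(g)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))
        out._backward = lambda g: (g, g)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))
        a, b = self.data, other.data
        out._backward = lambda g: (g * b, g * a)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))
        a, b = self.data, other.data
        out._backward = lambda g: (g / b, -g * a / (b * b))
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p):
        if not isinstance(p, (int, float)):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data**p, _prev=(self,))
        a = self.data
        out._backward = lambda g: (g * p * a ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))
        a, b = self.data, other.data
        out._backward = lambda g: (g @ b.T, a.T @ g)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            parts = idx if isinstance(idx, tuple) else (idx,)
            if any(isinstance(p, (list, np.ndarray)) for p in parts):
                np.add.at(full, idx, g)  # integer-array indices may repeat
            else:
                full[idx] += g
            return (full,)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        orig = self.data.shape
        out._backward = lambda g: (g.reshape(orig),)
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        shape = self.data.shape

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


# -- generic elementwise functions (Tensor or ndarray) ---------------------


def _unary(x, fval, fgrad):
    if isinstance(x, Tensor):
        out = Tensor(fval(x.data), _prev=(x,))
        a = x.data
        out._backward = lambda g: (g * fgrad(a),)
        return out
    return fval(np.asarray(x, dtype=np.float64))


def exp(x):
    return _unary(x, np.exp, np.exp)


def log(x):
    return _unary(x, np.log, lambda a: 1.0 / a)


def log1p(x):
    return _unary(x, np.log1p, lambda a: 1.0 / (1.0 + a))


def sqrt(x):
    return _unary(x, np.sqrt, lambda a: 0.5 / np.sqrt(a))


def _softplus_val(a):
    # log(1 + e^a), stable for large |a|
    return np.logaddexp(0.0, a)


def _sigmoid_val(a):
    return _sp.expit(a)


def softplus(x):
    return _unary(x, _softplus_val, _sigmoid_val)


def sigmoid(x):
    return _unary(x, _sigmoid_val, lambda a: _sigmoid_val(a) * (1.0 - _sigmoid_val(a)))


def lgamma(x):
    return _unary(x, _sp.gammaln, _sp.digamma)


def relu(x):
    return _unary(x, lambda a: np.maximum(a, 0.0), lambda a: (a > 0).astype(float))


def elu(x, alpha: float = 1.0):
    # evaluate exp only on the negative side to avoid spurious overflow
    return _unary(
        x,
        lambda a: np.where(a > 0, a, alpha * np.expm1(np.minimum(a, 0.0))),
        lambda a: np.where(a > 0, 1.0, alpha * np.exp(np.minimum(a, 0.0))),
    )


def logaddexp(a, b):
    """log(e^a + e^b); for Tensors both arguments must be finite."""
    if not _is_t(a, b):
        return np.logaddexp(a, b)
    a, b = _as_tensor(a), _as_tensor(b)
    return a + softplus(b - a)


def where(cond, a, b):
    """Select per element; ``cond`` is a plain boolean array (not differentiated)."""
    cond = np.asarray(cond, dtype=bool)
    if not _is_t(a, b):
        return np.where(cond, a, b)
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(np.where(cond, a.data, b.data), _prev=(a, b))
    out._backward = lambda g: (np.where(cond, g, 0.0), np.where(cond, 0.0, g))
    return out


def clip(x, lo: float, hi: float):
    """Clamp values; gradient passes only inside the interval."""
    if not isinstance(x, Tensor):
        return np.clip(np.asarray(x, dtype=np.float64), lo, hi)
    out = Tensor(np.clip(x.data, lo, hi), _prev=(x,))
    a = x.data
    out._backward = lambda g: (np.where((a >= lo) & (a <= hi), g, 0.0),)
    return out


def softmax_rows(x, axis: int = 1):
    """Row-wise softmax, numerically shifted by the (detached) row maximum."""
    if not isinstance(x, Tensor):
        x = np.asarray(x, dtype=np.float64)
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        return e / e.sum(axis=axis, keepdims=True)
    m = x.data.max(axis=axis, keepdims=True)  # constant shift; softmax invariant
    e = exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def concat_cols(parts):
    """Concatenate matrices along columns."""
    if not _is_t(*parts):
        return np.concatenate([np.asarray(p, dtype=np.float64) for p in parts], axis=1)
    parts = [_as_tensor(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=1), _prev=tuple(parts))
    widths = [p.data.shape[1] for p in parts]

    def bw(g):
        grads, c = [], 0
        for w in widths:
            grads.append(g[:, c : c + w])
            c += w
        return tuple(grads)

    out._backward = bw
    return out


def take_rows(x, idx):
    """Row gather (used for the negative-pair permutation)."""
    idx = np.asarray(idx, dtype=int)
    if not isinstance(x, Tensor):
        return np.asarray(x, dtype=np.float64)[idx]
    return x[idx]


def matmul(a, b):
    if _is_t(a, b):
        return _as_tensor(a) @ _as_tensor(b)
    return np.asarray(a) @ np.asarray(b)


def summ(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.asarray(x, dtype=np.float64).sum(axis=axis, keepdims=keepdims)


def mean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.asarray(x, dtype=np.float64).mean(axis=axis, keepdims=keepdims)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
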