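"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: every :class:`Tensor` wraps a float64 ndarray and
remembers how it was produced, so a single call to :meth:`Tensor.backward`
on a scalar accumulates ``d scalar / d leaf`` into every leaf created with
``requires_grad=True``.  Only the operations needed by the fuzzy network are
implemented (elementwise arithmetic, exp/log/tanh/sigmoid, axis reductions,
cumulative sums, slicing, stacking and clamping); broadcasting follows numpy
semantics with gradients summed over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return np.array(self.data, copy=True)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS; graphs can be deep for long epochs
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(stack_.pop())
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data**2)

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported; use exp/log otherwise")
        out = Tensor(self.data**exponent, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - val**2))

        out._backward = bw
        return out

    def sigmoid(self):
        # numerically stable two-sided form
        z = np.exp(-np.abs(self.data))
        val = np.where(self.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z))
        out = Tensor(val, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * val * (1.0 - val))

        out._backward = bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))

        out._backward = bw
        return out

    def softplus(self):
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                z = np.exp(-np.abs(self.data))
                sig = np.where(self.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z))
                self._accumulate(g * sig)

        out._backward = bw
        return out

    def clamp_max(self, limit: float):
        """min(self, limit); gradient passes where self <= limit (sub-gradient)."""
        mask = self.data <= limit
        out = Tensor(np.where(mask, self.data, limit), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def clamp_min(self, limit: float):
        mask = self.data >= limit
        out = Tensor(np.where(mask, self.data, limit), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def where_mask(self, mask: np.ndarray, fill: float):
        """Value where boolean ``mask`` holds, constant ``fill`` elsewhere."""
        mask = np.broadcast_to(mask, self.data.shape)
        out = Tensor(np.where(mask, self.data, fill), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(ge, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def cumsum(self, axis: int):
        out = Tensor(np.cumsum(self.data, axis=axis), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                rev = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
                self._accumulate(rev)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        out._backward = bw
        return out


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def bw(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(np.squeeze(piece, axis=axis))

    out._backward = bw
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of leaf tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
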