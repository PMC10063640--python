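"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based autodiff engine sized for the toy-scale
sequence encoder in :mod:`twix.model`: float64 throughout, 2-D matmul,
broadcasting elementwise ops, softmax/sigmoid primitives and basic
slicing/concatenation.  Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Tensor", "softmax", "concat", "grad_check"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, _parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _acc(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep for long batches)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw():
            self._acc(_unbroadcast(out.grad, self.data.shape))
            other._acc(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda: self._acc(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw():
            self._acc(_unbroadcast(out.grad * other.data, self.data.shape))
            other._acc(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, (self,))

        def bw():
            self._acc(out.grad * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        out = Tensor(self.data @ other.data, (self, other))

        def bw():
            self._acc(out.grad @ other.data.T)
            other._acc(self.data.T @ out.grad)

        out._backward = bw
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, (self,))
        out._backward = lambda: self._acc(out.grad.T)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda: self._acc(out.grad.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw():
            g = np.zeros_like(self.data)
            g[idx] += out.grad
            self._acc(g)

        out._backward = bw
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda: self._acc(out.grad * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda: self._acc(out.grad / self.data)
        return out

    def sigmoid(self):
        p = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(p, (self,))
        out._backward = lambda: self._acc(out.grad * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda: self._acc(out.grad * (self.data > 0.0))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through the interior only."""
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        inside = (self.data > lo) & (self.data < hi)
        out._backward = lambda: self._acc(out.grad * inside)
        return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, (x,))

    def bw():
        g = out.grad
        dot = (g * out.data).sum(axis=axis, keepdims=True)
        x._acc(out.data * (g - dot))

    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out.data.ndim
            idx[axis] = slice(a, b)
            t._acc(out.grad[tuple(idx)])

    out._backward = bw
    return out


def grad_check(fn, params: dict[str, Tensor], eps: float = 1e-6) -> float:
    """Max relative error between analytic and central-difference gradients.

    ``fn`` maps the parameter dict to a scalar :class:`Tensor`.  Used by the
    test suite to validate every op that the encoder composes.
    """
    for t in params.values():
        t.zero_grad()
    fn(params).backward()
    analytic = {k: (t.grad.copy() if t.grad is not None else np.zeros_like(t.data))
                for k, t in params.items()}
    worst = 0.0
    for k, t in params.items():
        flat = t.data.ravel()
        num = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(fn(params).data)
            flat[i] = orig - eps
            lo = float(fn(params).data)
            flat[i] = orig
            num[i] = (hi - lo) / (2.0 * eps)
        a = analytic[k].ravel()
        # floor the denominator so finite-difference noise on exactly-zero
        # gradients (e.g. softmax-invariant key biases) is not flagged
        denom = np.maximum(np.abs(a) + np.abs(num), 1e-4)
        worst = max(worst, float(np.max(np.abs(a - num) / denom)))
    return worst
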