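"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package are small (MLP image encoders, one recurrent
cell, linear heads), so a dynamic tape over numpy suffices: every operation
records a backward closure, and :meth:`Tensor.backward` walks the tape in
reverse topological order.  All arrays are float64.

Only the operations the models need are implemented; each backward rule
handles numpy broadcasting by summing gradients over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "exp",
    "log",
    "sin",
    "cos",
    "tanh",
    "sigmoid",
    "softplus",
    "relu",
    "log_softmax",
    "Adam",
    "glorot",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        order, seen, stack = [], set(), [(self, False)]
        while stack:  # iterative post-order DFS
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(g)
                if other.requires_grad:
                    other._accumulate(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(g * other.data)
                if other.requires_grad:
                    other._accumulate(g * self.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(g / other.data)
                if other.requires_grad:
                    other._accumulate(-g * self.data / other.data**2)
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1.0)
            )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g)
            out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))
        if out.requires_grad:
            def backward(g):
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)
            out._backward = backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.T)
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        if out.requires_grad:
            def backward(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


# ----------------------------------------------------------------------
# elementwise functions: dispatch on Tensor vs plain array/scalar


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def exp(x):
    if not _is_tensor(x):
        return np.exp(x)
    out = Tensor(np.exp(x.data), _parents=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * out.data)
    return out


def log(x):
    if not _is_tensor(x):
        return np.log(x)
    out = Tensor(np.log(x.data), _parents=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g / x.data)
    return out


def sin(x):
    if not _is_tensor(x):
        return np.sin(x)
    out = Tensor(np.sin(x.data), _parents=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * np.cos(x.data))
    return out


def cos(x):
    if not _is_tensor(x):
        return np.cos(x)
    out = Tensor(np.cos(x.data), _parents=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(-g * np.sin(x.data))
    return out


def tanh(x):
    if not _is_tensor(x):
        return np.tanh(x)
    out = Tensor(np.tanh(x.data), _parents=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * (1.0 - out.data**2))
    return out


def sigmoid(x):
    if not _is_tensor(x):
        return 1.0 / (1.0 + np.exp(-x))
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(val, _parents=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * val * (1.0 - val))
    return out


def softplus(x):
    if not _is_tensor(x):
        return np.logaddexp(0.0, x)
    out = Tensor(np.logaddexp(0.0, x.data), _parents=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g / (1.0 + np.exp(-x.data)))
    return out


def relu(x):
    if not _is_tensor(x):
        return np.maximum(0.0, x)
    out = Tensor(np.maximum(0.0, x.data), _parents=(x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * (x.data > 0.0))
    return out


def concat(tensors, axis=-1):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = backward
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtract a detached max for numerical stability; its gradient is zero
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - log(exp(shifted).sum(axis=axis, keepdims=True))


# ----------------------------------------------------------------------


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=0.002, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
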