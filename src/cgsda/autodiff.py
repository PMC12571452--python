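"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in this package is a pair of graph neural network branches with
a handful of dense operations (matrix products, gating nonlinearities,
concatenation, a Gram-matrix decoder).  This module provides exactly the
tensor operations those layers need, with gradients accumulated by a
topological backward sweep.  Everything is float64 and CPU-only; graphs
of a few hundred nodes train in seconds.

Gradient correctness is enforced by finite-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "matmul", "relu", "sigmoid", "tanh",
           "take_pairs", "dropout", "Adam"]


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ---------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)

        def back(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return _node(self.data + other.data, (self, other), back)

    def __mul__(self, other):
        other = _as_tensor(other)

        def back(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return _node(self.data * other.data, (self, other), back)

    def __neg__(self):
        def back(g):
            self._accumulate(-g)

        return _node(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rmul__(self, other):
        return self * other

    def __radd__(self, other):
        return self + other

    def __rsub__(self, other):
        return (-self) + other

    @property
    def T(self):
        def back(g):
            self._accumulate(g.T)

        return _node(self.data.T, (self,), back)

    def mean(self):
        n = self.data.size

        def back(g):
            self._accumulate(np.full_like(self.data, float(g) / n))

        return _node(self.data.mean(), (self,), back)

    def log(self):
        def back(g):
            self._accumulate(g / self.data)

        return _node(np.log(self.data), (self,), back)

    def clamp_min(self, lo: float):
        mask = self.data >= lo

        def back(g):
            self._accumulate(g * mask)

        return _node(np.maximum(self.data, lo), (self,), back)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, back) -> Tensor:
    if any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, parents=parents, backward=back)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def back(g):
        if a.requires_grad or a._parents:
            a._accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b._accumulate(a.data.T @ g)

    return _node(a.data @ b.data, (a, b), back)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), back)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0

    def back(g):
        x._accumulate(g * mask)

    return _node(x.data * mask, (x,), back)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    out[~pos] = ex / (1.0 + ex)

    def back(g):
        x._accumulate(g * out * (1.0 - out))

    return _node(out, (x,), back)


def tanh(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = np.tanh(x.data)

    def back(g):
        x._accumulate(g * (1.0 - out * out))

    return _node(out, (x,), back)


def take_pairs(x: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Gather matrix entries x[rows[i], cols[i]] into a vector."""
    x = _as_tensor(x)
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)

    def back(g):
        full = np.zeros_like(x.data)
        np.add.at(full, (rows, cols), g)
        x._accumulate(full)

    return _node(x.data[rows, cols], (x,), back)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    x = _as_tensor(x)
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)

    def back(g):
        x._accumulate(g * mask)

    return _node(x.data * mask, (x,), back)


class Adam:
    """Adaptive moment estimation with decoupled-from-nothing L2 weight decay
    (the decay is added to the gradient, the common coupled formulation)."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 weight_decay: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
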