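"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations needed by the classifiers in this package:
dense algebra (matmul, broadcast add/mul/div, pow), the nonlinearities
(ELU, ReLU, sigmoid, log), reductions (sum, mean), and the two sparse
primitives of message passing — gathering rows by edge source and
scatter-adding messages at edge targets.  Gradients flow to any leaf tensor
marked ``requires_grad``, which covers model weights (training), node
features and edge weights (integrated-gradients attribution).

Single-threaded and deterministic: identical inputs give identical gradients.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over broadcast dimensions so it matches `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(t.requires_grad or t._prev for t in prev):
            out.requires_grad = True
            out._prev = prev
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- reductions and shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._accum(g.reshape(self.data.shape))

        return self._make(out_data, (self,), backward)

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        out_data = self.data[:, start:stop]

        def backward(g):
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        out_data = np.where(self.data > 0, self.data, alpha * np.expm1(self.data))

        def backward(g):
            self._accum(g * np.where(self.data > 0, 1.0, alpha * np.exp(self.data)))

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def abs(self) -> "Tensor":
        out_data = np.abs(self.data)

        def backward(g):
            self._accum(g * np.sign(self.data))

        return self._make(out_data, (self,), backward)

    def clamp(self, lo: float, hi: float) -> "Tensor":
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            self._accum(g * ((self.data >= lo) & (self.data <= hi)))

        return self._make(out_data, (self,), backward)

    # -- sparse message-passing primitives ---------------------------------
    def gather_rows(self, index: np.ndarray) -> "Tensor":
        index = np.asarray(index, dtype=np.int64)
        out_data = self.data[index]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    def segment_sum(self, index: np.ndarray, n_segments: int) -> "Tensor":
        """Sum rows into ``n_segments`` bins given per-row target indices."""
        index = np.asarray(index, dtype=np.int64)
        out_data = np.zeros((n_segments,) + self.data.shape[1:])
        np.add.at(out_data, index, self.data)

        def backward(g):
            self._accum(g[index])

        return self._make(out_data, (self,), backward)

    # -- graph traversal ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat_cols(tensors: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along columns with gradient routing."""
    data = np.concatenate([t.data for t in tensors], axis=1)
    out = Tensor(data)
    offsets = np.cumsum([0] + [t.data.shape[1] for t in tensors])

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            t._accum(g[:, a:b])

    if any(t.requires_grad or t._prev for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of leaf tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
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
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
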