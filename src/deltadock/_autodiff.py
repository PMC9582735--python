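"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core behind the graph neural networks: a `Tensor` wraps
an ndarray and records enough of the computation graph to backpropagate exact
gradients. Only the operations the models need are implemented — broadcasted
arithmetic, matmul, sparse-constant matmul, ReLU/LeakyReLU, exp/sqrt/power,
reductions, row gather and segment scatter (for attention softmax over edges).

Gradients are accumulated in ``Tensor.grad`` by :meth:`Tensor.backward`, which
runs a topological sort of the recorded graph. Constants (``requires_grad=False``
leaves) never store gradients.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "relu", "leaky_relu", "spmm", "gather", "segment_sum", "edge_aggregate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    # -- graph bookkeeping --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep chains exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self):
        value = np.exp(self.data)
        out = Tensor(value, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * value)
        return out

    def sqrt(self):
        value = np.sqrt(self.data)
        out = Tensor(value, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / (2 * value))
        return out

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * mask)
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(x.data > 0, 1.0, slope)
    out = Tensor(x.data * factor, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * factor)
    return out


def spmm(matrix: sp.spmatrix, x: Tensor) -> Tensor:
    """Constant sparse matrix times tensor: ``matrix @ x``."""
    out = Tensor(matrix @ x.data, parents=(x,))
    mt = matrix.T.tocsr()
    out._backward = lambda g: x.requires_grad and x._accumulate(mt @ g)
    return out


def gather(x: Tensor, index: np.ndarray) -> Tensor:
    """Row gather ``x[index]``; backward scatter-adds into the source rows."""
    out = Tensor(x.data[index], parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        acc = np.zeros_like(x.data)
        np.add.at(acc, index, g)
        x._accumulate(acc)

    out._backward = backward
    return out


def segment_sum(x: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given per-row segment ids."""
    value = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(value, segments, x.data)
    out = Tensor(value, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g[segments])
    return out


def edge_aggregate(
    alpha: Tensor, h: Tensor, src: np.ndarray, dst: np.ndarray, n_nodes: int
) -> Tensor:
    """Attention-weighted neighbour aggregation over an edge list.

    ``out[n] = sum over edges e with dst[e]==n of alpha[e] * h[src[e]]``,
    with ``alpha`` of shape (E, 1) and ``h`` of shape (N, K).
    """
    value = np.zeros((n_nodes, h.data.shape[1]))
    np.add.at(value, dst, alpha.data * h.data[src])
    out = Tensor(value, parents=(alpha, h))

    def backward(g):
        if alpha.requires_grad:
            galpha = (g[dst] * h.data[src]).sum(axis=1, keepdims=True)
            alpha._accumulate(galpha)
        if h.requires_grad:
            gh = np.zeros_like(h.data)
            np.add.at(gh, src, alpha.data * g[dst])
            h._accumulate(gh)

    out._backward = backward
    return out
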