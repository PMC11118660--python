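"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the graph-transformer model needs:
dense linear algebra (matmul, broadcasting arithmetic), elementwise
nonlinearities, reductions, and the two sparse message-passing primitives
(``gather_rows`` and ``segment_sum``) from which edge-softmax attention is
composed. Gradients are accumulated by topological-order backpropagation.

The engine is deliberately small: float64 throughout, no graph retention
across backward calls, no higher-order derivatives.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["Tensor", "Parameter", "concat", "no_grad"]


def _scatter_matrix(index: np.ndarray, n_rows: int) -> sparse.csr_matrix:
    """(n_rows x len(index)) one-hot matrix: left-multiplication scatter-adds
    rows of a dense array into ``n_rows`` buckets. Much faster than
    ``np.add.at`` for the repeated fixed-index scatters of message passing."""
    n = len(index)
    return sparse.csr_matrix(
        (np.ones(n), (index, np.arange(n))), shape=(n_rows, n)
    )


def _scatter_add(P: sparse.csr_matrix, values: np.ndarray) -> np.ndarray:
    flat = values.reshape(values.shape[0], -1)
    out = P @ flat
    return out.reshape((P.shape[0],) + values.shape[1:])


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    @staticmethod
    def _as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._as_tensor(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward, req)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return (-g,)

        return self._make(-self.data, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        other = self._as_tensor(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        return self._make(self.data - other.data, (self, other), backward, req)

    def __rsub__(self, other):
        return self._as_tensor(other) - self

    def __mul__(self, other):
        other = self._as_tensor(other)
        req = self.requires_grad or other.requires_grad
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, self.shape), _unbroadcast(g * a, other.shape))

        return self._make(a * b, (self, other), backward, req)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._as_tensor(other)
        req = self.requires_grad or other.requires_grad
        a, b = self.data, other.data

        def backward(g):
            return (
                _unbroadcast(g / b, self.shape),
                _unbroadcast(-g * a / (b * b), other.shape),
            )

        return self._make(a / b, (self, other), backward, req)

    def __pow__(self, exponent: float):
        a = self.data

        def backward(g):
            return (g * exponent * a ** (exponent - 1),)

        return self._make(a**exponent, (self,), backward, self.requires_grad)

    def __matmul__(self, other):
        other = self._as_tensor(other)
        req = self.requires_grad or other.requires_grad
        a, b = self.data, other.data

        def backward(g):
            return (g @ b.T, a.T @ g)

        return self._make(a @ b, (self, other), backward, req)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward, self.requires_grad)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._make(out_data, (self,), backward, self.requires_grad)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), backward, self.requires_grad)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * s * (1.0 - s),)

        return self._make(s, (self,), backward, self.requires_grad)

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shape ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, shape).copy(),)

        return self._make(out_data, (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return self._make(self.data.reshape(*shape), (self,), backward, self.requires_grad)

    # -- sparse message-passing primitives ------------------------------------

    def gather_rows(self, index: np.ndarray, scatter: sparse.csr_matrix | None = None):
        """Select rows (axis 0) by integer index; grad scatter-adds back.

        ``scatter`` may supply a precomputed one-hot scatter matrix for the
        backward pass (cached per edge set by the model)."""
        index = np.asarray(index, dtype=np.intp)
        n_rows = self.shape[0]
        if self.requires_grad and scatter is None:
            scatter = _scatter_matrix(index, n_rows)

        def backward(g):
            return (_scatter_add(scatter, g),)

        return self._make(self.data[index], (self,), backward, self.requires_grad)

    def segment_sum(
        self,
        segment_ids: np.ndarray,
        num_segments: int,
        scatter: sparse.csr_matrix | None = None,
    ):
        """Sum rows into ``num_segments`` buckets along axis 0."""
        segment_ids = np.asarray(segment_ids, dtype=np.intp)
        if scatter is None:
            scatter = _scatter_matrix(segment_ids, num_segments)
        out_data = _scatter_add(scatter, self.data)

        def backward(g):
            return (g[segment_ids],)

        return self._make(out_data, (self,), backward, self.requires_grad)

    def weighted_masked_exp(self, weights: np.ndarray, shift: np.ndarray) -> "Tensor":
        """Fused softmax numerator: w * exp(x - shift) where w > 0, else 0.

        ``weights`` and ``shift`` are constants (shift detached for
        stability); the derivative w.r.t. x equals the output itself.
        """
        mask = weights > 0
        with np.errstate(over="ignore"):
            out_data = np.where(
                mask, weights * np.exp(np.minimum(self.data - shift, 700.0)), 0.0
            )

        def backward(g):
            return (g * out_data,)

        return self._make(out_data, (self,), backward, self.requires_grad)

    def transpose2d(self) -> "Tensor":
        def backward(g):
            return (g.T,)

        return self._make(self.data.T, (self,), backward, self.requires_grad)

    def edge_dot(self, other: "Tensor") -> "Tensor":
        """Fused per-edge, per-head inner product: (E,H,D),(E,H,D) -> (E,H)."""
        a, b = self.data, other.data
        req = self.requires_grad or other.requires_grad

        def backward(g):
            return (g[:, :, None] * b, g[:, :, None] * a)

        return self._make(
            np.einsum("ehd,ehd->eh", a, b), (self, other), backward, req
        )

    def scale_rows(self, scale: "Tensor") -> "Tensor":
        """Fused per-edge, per-head scaling: (E,H,D) * (E,H) -> (E,H,D)."""
        v, s = self.data, scale.data
        req = self.requires_grad or scale.requires_grad

        def backward(g):
            return (g * s[:, :, None], np.einsum("ehd,ehd->eh", g, v))

        return self._make(v * s[:, :, None], (self, scale), backward, req)

    # -- backward pass --------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                # non-inplace accumulation: returned grads may alias views
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self):
        self.grad = None


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    tensors = [Tensor._as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tuple(tensors), backward, req)


class no_grad:
    """Context marker for eval-mode passes (the engine builds no graph for
    tensors that do not require grad; this exists for API symmetry)."""

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad
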