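"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the affinity model needs: dense linear
algebra, elementwise nonlinearities, gather/segment reductions for sparse
message passing, and numerically stable primitives for the losses.  Gradients
are accumulated by a topological backward sweep over the recorded tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "segment_softmax",
    "softplus",
    "stack_rows",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # Added leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Broadcast singleton axes
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        """The value of a single-element tensor as a Python float."""
        return float(self.data.reshape(-1)[0])

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        # Iterative DFS with explicit post-order to avoid recursion limits.
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if not node.requires_grad:
                continue
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- construction helper ------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    self._accum(g * b)
                elif b.ndim == 1:  # (n,k) @ (k,) -> (n,)
                    self._accum(np.outer(g, b))
                else:  # (..,k) @ (k,m)
                    self._accum((np.atleast_2d(g) @ b.T).reshape(a.shape))
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    other._accum(g * a)
                elif a.ndim == 1:  # (k,) @ (k,m) -> (m,)
                    other._accum(np.outer(a, g))
                else:  # (n,k) @ (k,..)
                    gb = a.T @ np.atleast_2d(g).reshape(a.shape[0], -1)
                    other._accum(gb.reshape(b.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(ge, self.data.shape).copy())

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_rows(self):
        """Elementwise maximum over axis 0 (rows); gradient flows to argmax."""
        idx = np.argmax(self.data, axis=0)
        out_data = self.data[idx, np.arange(self.data.shape[1])]

        def backward(g):
            gx = np.zeros_like(self.data)
            gx[idx, np.arange(self.data.shape[1])] = g
            self._accum(gx)

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities -----------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - y**2))

        return Tensor._make(y, (self,), backward)

    def sigmoid(self):
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            self._accum(g * y * (1.0 - y))

        return Tensor._make(y, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        mult = np.where(mask, 1.0, slope)

        def backward(g):
            self._accum(g * mult)

        return Tensor._make(self.data * mult, (self,), backward)

    def asinh(self):
        def backward(g):
            self._accum(g / np.sqrt(1.0 + self.data**2))

        return Tensor._make(np.arcsinh(self.data), (self,), backward)

    def exp(self):
        y = np.exp(self.data)

        def backward(g):
            self._accum(g * y)

        return Tensor._make(y, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)


# -- free functions ---------------------------------------------------------


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably; d/dx = sigmoid(x)."""
    d = x.data
    y = np.maximum(d, 0.0) + np.log1p(np.exp(-np.abs(d)))

    def backward(g):
        x._accum(g * (0.5 * (1.0 + np.tanh(0.5 * d))))

    return Tensor._make(y, (x,), backward)


def spmm(A, At, x: Tensor) -> Tensor:
    """Multiply by a fixed sparse matrix: A @ x, with A^T supplied for the
    backward pass.  Used for gather/scatter over static graph structure."""

    def backward(g):
        x._accum(At @ g)

    return Tensor._make(A @ x.data, (x,), backward)


def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Fused affine transform x @ W + b (x: (n,k) or (k,), W: (k,m), b: (m,))."""
    out = x.data @ W.data + b.data

    def backward(g):
        if x.requires_grad:
            x._accum(g @ W.data.T)
        if W.requires_grad:
            if x.data.ndim == 1:
                W._accum(np.outer(x.data, g))
            else:
                W._accum(x.data.T @ g)
        if b.requires_grad:
            b._accum(g.sum(axis=0) if g.ndim == 2 else g)

    return Tensor._make(out, (x, W, b), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows x[idx]; scatter-add gradient."""
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        x._accum(gx)

    return Tensor._make(x.data[idx], (x,), backward)


def segment_sum(x: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of x into n_segments buckets given per-row segment ids."""
    seg = np.asarray(seg, dtype=np.intp)
    out = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(out, seg, x.data)

    def backward(g):
        x._accum(g[seg])

    return Tensor._make(out, (x,), backward)


def segment_softmax(scores: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a score vector within each segment (per-node attention)."""
    seg = np.asarray(seg, dtype=np.intp)
    # Subtract the (detached) per-segment max for stability; the subtraction
    # constant does not change the softmax value or its gradient.
    smax = np.full(n_segments, -np.inf)
    np.maximum.at(smax, seg, scores.data)
    shifted = scores - Tensor(smax[seg])
    ex = shifted.exp()
    denom = segment_sum(ex, seg, n_segments)
    return ex / gather(denom, seg)


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor (axis 0)."""

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(g[i])

    return Tensor._make(
        np.stack([t.data for t in tensors]), tuple(tensors), backward
    )
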