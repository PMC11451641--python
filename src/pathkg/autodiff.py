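"""Minimal reverse-mode automatic differentiation over numpy arrays.

The message-passing model needs gradients for training (Eq.-style NLL loss)
and for edge-importance explanations, but nothing close to a full deep-learning
framework: a handful of elementwise ops, matrix products, gather/scatter along
the edge index, segment reductions and layer normalization suffice.  This
module implements exactly that: a ``Tensor`` wrapping a float64 ndarray, a
tape of parent links, and a topological backward pass.

Broadcasting is supported for ``+``, ``-`` and ``*``; gradients of broadcast
operands are summed back to the operand's shape.  All computation is float64
and single-threaded, which makes runs bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    data:
        Array (or scalar) value; stored as float64.
    requires_grad:
        Whether gradients should be accumulated into ``.grad`` during
        :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape), dtype=np.float64)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape))

        return Tensor._make(self.data - other.data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        """2-D @ 2-D or (..., m, k) @ (k, n) matrix product."""
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic; logits clamped to avoid overflow
        z = np.clip(self.data, -500.0, 500.0)
        s = 1.0 / (1.0 + np.exp(-z))
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        return Tensor._make(r, (self,), lambda g: (g * 0.5 / np.maximum(r, 1e-300),))

    def cos(self) -> "Tensor":
        return Tensor._make(np.cos(self.data), (self,), lambda g: (-g * np.sin(self.data),))

    def sin(self) -> "Tensor":
        return Tensor._make(np.sin(self.data), (self,), lambda g: (g * np.cos(self.data),))

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out  # subgradient split among ties

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            counts = mask.sum(axis=axis, keepdims=True)
            return (gg * mask / counts,)

        return Tensor._make(out if keepdims else out.squeeze(axis), (self,), backward)

    # -- indexing / reshaping -------------------------------------------------

    def gather_rows(self, index: np.ndarray, axis: int = 0) -> "Tensor":
        """Take rows along `axis` by integer index (duplicates allowed)."""
        out = np.take(self.data, index, axis=axis)

        def backward(g):
            gi = np.zeros_like(self.data)
            if axis == 0:
                np.add.at(gi, index, g)
            elif axis == 1:
                np.add.at(gi, (slice(None), index), g)
            else:  # pragma: no cover - not used beyond axis 1
                raise NotImplementedError
            return (gi,)

        return Tensor._make(out, (self,), backward)

    def scatter_add(self, index: np.ndarray, num_segments: int, axis: int = 0) -> "Tensor":
        """Segment-sum rows along `axis` into `num_segments` bins."""
        shape = list(self.data.shape)
        shape[axis] = num_segments
        out = np.zeros(shape, dtype=np.float64)
        if axis == 0:
            np.add.at(out, index, self.data)
        elif axis == 1:
            np.add.at(out, (slice(None), index), self.data)
        else:  # pragma: no cover
            raise NotImplementedError

        def backward(g):
            return (np.take(g, index, axis=axis),)

        return Tensor._make(out, (self,), backward)

    def segment_max(self, index: np.ndarray, num_segments: int, axis: int = 1) -> "Tensor":
        """Segment-wise elementwise max along `axis`; empty segments get 0."""
        shape = list(self.data.shape)
        shape[axis] = num_segments
        out = np.full(shape, -np.inf)
        if axis == 1:
            np.maximum.at(out, (slice(None), index), self.data)
        elif axis == 0:
            np.maximum.at(out, index, self.data)
        else:  # pragma: no cover
            raise NotImplementedError
        empty = ~np.isfinite(out)
        out[empty] = 0.0
        winners = np.take(out, index, axis=axis) == self.data

        def backward(g):
            gg = np.take(g, index, axis=axis) * winners
            # split ties evenly
            counts = np.zeros(shape)
            if axis == 1:
                np.add.at(counts, (slice(None), index), winners.astype(np.float64))
            else:
                np.add.at(counts, index, winners.astype(np.float64))
            denom = np.take(np.maximum(counts, 1.0), index, axis=axis)
            return (gg / denom,)

        return Tensor._make(out, (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def __getitem__(self, key):
        def backward(g):
            gi = np.zeros_like(self.data)
            np.add.at(gi, key, g)
            return (gi,)

        return Tensor._make(self.data[key], (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed gradient: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (layers x edges)
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

        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if parent.requires_grad:
                    parent._accumulate(g)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def backward(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
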