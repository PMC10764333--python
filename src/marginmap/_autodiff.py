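"""Minimal vectorized reverse-mode autodiff on numpy arrays.

Just enough machinery for the patch CNN and the graph-attention network:
broadcast-aware arithmetic, matmul, gather/scatter-add (graph message
passing and im2col convolution), and stable log-sum-exp composition.
Float64 throughout; graphs are built dynamically and freed after
``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "logsumexp_rows", "segment_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward()
        for t in topo:  # free the graph
            t._backward = None
            t._prev = ()

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw():
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = bw
        return out

    def leaky_relu(self, slope=0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0, slope))

        out._backward = bw
        return out

    def elu(self, alpha=1.0):
        e = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(self.data > 0, self.data, e), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0, e + alpha))

        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _prev=(self,))
        inv = np.argsort(axes)

        def bw():
            if self.requires_grad:
                self._accum(out.grad.transpose(*inv))

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def gather(self, idx):
        """``out = data[idx]`` for an integer index array of any shape
        (indexing the first axis, or flat data for conv im2col)."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], _prev=(self,))

        def bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = bw
        return out

    def scatter_add(self, idx, size: int):
        """Segment sum along axis 0: ``out[k] = sum_{i: idx[i]=k} data[i]``."""
        idx = np.asarray(idx)
        shape = (size,) + self.data.shape[1:]
        acc = np.zeros(shape)
        np.add.at(acc, idx, self.data)
        out = Tensor(acc, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad[idx])

        out._backward = bw
        return out


def concat(tensors, axis=0):
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = bw
    return out


def logsumexp_rows(x: Tensor) -> Tensor:
    """Row-wise log-sum-exp of a 2-D tensor, numerically stabilized with a
    constant (detached) row maximum."""
    m = x.data.max(axis=1, keepdims=True)
    return ((x - m).exp().sum(axis=1, keepdims=True)).log() + m


def segment_softmax(e: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Softmax of edge scores ``e`` (shape (E,) or (E,1)) within segments
    ``seg`` (e.g. destination node of each edge); stabilized per segment."""
    flat = e if e.data.ndim == 1 else e.reshape(-1)
    m = np.full(n_seg, -np.inf)
    np.maximum.at(m, seg, flat.data)
    ex = (flat - m[seg]).exp()
    denom = ex.scatter_add(seg, n_seg)
    return ex / denom.gather(seg)
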