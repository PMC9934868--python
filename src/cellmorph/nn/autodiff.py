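"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the encoders and losses need: broadcasting
arithmetic, matmul, gather/scatter (for im2col convolution and k-NN graph
convolution), axis reductions (sum / mean / max), ELU, exp/log/pow, reshape /
transpose / concatenate and zero padding.  Gradients flow through a
dynamically recorded tape; ``Tensor.backward()`` runs the tape in reverse
topological order.

All data is kept in float32 unless the caller passes float64.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    for _ in range(nd):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32 if np.asarray(data).dtype
                               not in (np.float32, np.float64) else None)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- tape ---------------------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.requires_grad = any(p.requires_grad for p in parents)
        out.grad = None
        out._parents = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            if not t._parents:  # leaf (parameter or input)
                t.grad = g if t.grad is None else t.grad + g

    # -- helpers ------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out_data = self.data + other.data
        def backward(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))
        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return ((self, -g),)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out_data = self.data * other.data
        def backward(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))
        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.data.dtype)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return _as_tensor(other, self.data.dtype) * self.pow(-1.0)

    def pow(self, p: float):
        out_data = self.data ** p
        def backward(g):
            return ((self, g * p * self.data ** (p - 1.0)),)
        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            return ((self, g * out_data),)
        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)
        def backward(g):
            return ((self, g / self.data),)
        return Tensor._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        out_data = np.where(self.data > 0, self.data,
                            alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        def backward(g):
            local = np.where(self.data > 0, 1.0, out_data + alpha)
            return ((self, g * local.astype(g.dtype)),)
        return Tensor._make(out_data, (self,), backward)

    # -- linear algebra -----------------------------------------------------

    def __matmul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out_data = self.data @ other.data
        def backward(g):
            return ((self, g @ other.data.T), (other, self.data.T @ g))
        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        def backward(g):
            return ((self, g.reshape(old)),)
        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)
        def backward(g):
            return ((self, g.transpose(inv)),)
        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]
        shape = self.data.shape
        def backward(g):
            full = np.zeros(shape, dtype=g.dtype)
            full[key] = g
            return ((self, full),)
        return Tensor._make(out_data, (self,), backward)

    def pad(self, pad_width):
        out_data = np.pad(self.data, pad_width)
        sl = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, self.data.shape))
        def backward(g):
            return ((self, g[sl]),)
        return Tensor._make(out_data, (self,), backward)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape
        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, shape).copy()),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g2, shape).copy()),)
        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        am = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(am, axis),
                                      axis=axis).squeeze(axis)
        shape = self.data.shape
        def backward(g):
            full = np.zeros(shape, dtype=g.dtype)
            np.put_along_axis(full, np.expand_dims(am, axis),
                              np.expand_dims(g, axis), axis=axis)
            return ((self, full),)
        return Tensor._make(out_data, (self,), backward)


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    t = Tensor(np.asarray(x, dtype=dtype))
    return t


def concat(tensors: list, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    def backward(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            outs.append((t, g[tuple(sl)]))
        return tuple(outs)
    return Tensor._make(out_data, tuple(tensors), backward)


def gather(t: Tensor, flat_index: np.ndarray) -> Tensor:
    """Fancy gather from the flattened tensor; backward scatter-adds."""
    flat_index = np.asarray(flat_index)
    out_data = t.data.reshape(-1)[flat_index]
    shape = t.data.shape
    def backward(g):
        full = np.zeros(int(np.prod(shape)), dtype=g.dtype)
        np.add.at(full, flat_index.reshape(-1), g.reshape(-1))
        return ((t, full.reshape(shape)),)
    return Tensor._make(out_data, (t,), backward)
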