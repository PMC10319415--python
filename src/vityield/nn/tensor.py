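"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports the operations needed by the model zoo: broadcasting arithmetic,
batched matmul, reductions, reshapes, slicing, concatenation, softmax
building blocks, GELU/ReLU/tanh/sigmoid, and 2-D convolution / max-pooling
via im2col. Gradients accumulate into ``Tensor.grad`` after ``backward()``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were size-1 in the original
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)
        # topological order
        topo, visited = [], set()
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
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        grads = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:
                node.grad = g if node.grad is None else node.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        data = self.data + other.data

        def bwd(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return self._make(data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        data = self.data * other.data

        def bwd(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return self._make(data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        data = self.data / other.data

        def bwd(g):
            return ((self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.data.shape)))

        return self._make(data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        data = self.data ** p

        def bwd(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return self._make(data, (self,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)
        data = self.data @ other.data

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            elif a.ndim == 1:
                ga = (g[..., None, :] @ np.swapaxes(b, -1, -2)).reshape(a.shape)
                gb = a[:, None] @ g[..., None, :] if b.ndim == 2 else \
                    _unbroadcast(a[:, None] * g[..., None, :], b.shape)
            elif b.ndim == 1:
                ga = g[..., None] @ b[None, :]
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g[..., None],
                                  b.shape + (1,)).reshape(b.shape)
            else:
                ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return ((self, ga), (other, gb))

        return self._make(data, (self, other), bwd)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                gg = np.broadcast_to(g, self.data.shape)
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                gg = np.broadcast_to(g2, self.data.shape)
            return ((self, gg.copy()),)

        return self._make(data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        data = self.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            d = data if keepdims or axis is None else np.expand_dims(data, axis)
            mask = (self.data == d).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True) if axis is not None \
                else mask.sum()
            g2 = g if keepdims or axis is None else np.expand_dims(g, axis)
            return ((self, mask * g2),)

        return self._make(data, (self,), bwd)

    # -------------------------------------------------------------- elementwise
    def exp(self):
        data = np.exp(self.data)
        return self._make(data, (self,), lambda g: ((self, g * data),))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: ((self, g / self.data),))

    def sqrt(self):
        data = np.sqrt(self.data)
        return self._make(data, (self,), lambda g: ((self, g / (2 * data)),))

    def tanh(self):
        data = np.tanh(self.data)
        return self._make(data, (self,),
                          lambda g: ((self, g * (1 - data ** 2)),))

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(data, (self,),
                          lambda g: ((self, g * data * (1 - data)),))

    def relu(self):
        data = np.maximum(self.data, 0.0)
        return self._make(data, (self,),
                          lambda g: ((self, g * (self.data > 0)),))

    def gelu(self):
        """Exact GELU: x * Phi(x) with the Gaussian CDF."""
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x / np.sqrt(2.0)))
        data = x * cdf

        def bwd(g):
            pdf = np.exp(-0.5 * x ** 2) / np.sqrt(2 * np.pi)
            return ((self, g * (cdf + x * pdf)),)

        return self._make(data, (self,), bwd)

    # ---------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)
        src = self.data.shape
        return self._make(data, (self,),
                          lambda g: ((self, g.reshape(src)),))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return self._make(self.data.transpose(axes), (self,),
                          lambda g: ((self, g.transpose(inv)),))

    def swapaxes(self, a, b):
        def bwd(g):
            return ((self, np.swapaxes(g, a, b)),)
        return self._make(np.swapaxes(self.data, a, b), (self,), bwd)

    def __getitem__(self, idx):
        data = self.data[idx]

        def bwd(g):
            gg = np.zeros_like(self.data)
            np.add.at(gg, idx, g)
            return ((self, gg),)

        return self._make(data, (self,), bwd)

    # ------------------------------------------------------------ compound ops
    def softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        mu = self.mean(axis=-1, keepdims=True)
        xc = self - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + eps).sqrt()
        return xhat * gamma + beta

    def dropout(self, rate: float, rng: np.random.Generator,
                training: bool) -> "Tensor":
        if not training or rate <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        return self * Tensor(mask)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor._make(data, tuple(tensors), bwd)


def stack(tensors, axis=0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple((t, np.squeeze(p, axis=axis))
                     for t, p in zip(tensors, parts))

    return Tensor._make(data, tuple(tensors), bwd)
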