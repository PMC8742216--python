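"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the recurrent models need: broadcasted
arithmetic, matmul, tanh/sigmoid/softplus, abs, exp, slicing, stacking,
axis reductions and stable softmax.  Gradients for broadcasted operands
are reduced back to the operand's shape.  float64 throughout; CPU is
the reference execution.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g

    # -- operations -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        return Tensor._make(
            self.data + other.data, (self, other),
            lambda g: ((self, _unbroadcast(g, self.shape)),
                       (other, _unbroadcast(g, other.shape))))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor._make(
            self.data * other.data, (self, other),
            lambda g: ((self, _unbroadcast(g * other.data, self.shape)),
                       (other, _unbroadcast(g * self.data, other.shape))))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor._make(
            self.data / other.data, (self, other),
            lambda g: ((self, _unbroadcast(g / other.data, self.shape)),
                       (other, _unbroadcast(-g * self.data / other.data ** 2,
                                            other.shape))))

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            return ((self, _unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                        self.shape)),
                    (other, _unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                         other.shape)))
        return Tensor._make(self.data @ other.data, (self, other), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return ((self, full),)
        return Tensor._make(self.data[idx], (self,), backward)

    def reshape(self, *shape):
        return Tensor._make(
            self.data.reshape(*shape), (self,),
            lambda g: ((self, g.reshape(self.shape)),))

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.shape).copy()),)
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g: ((self, g * (1.0 - out_data ** 2)),))

    def sigmoid(self):
        out_data = sigmoid_np(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g: ((self, g * out_data * (1.0 - out_data)),))

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: ((self, g * out_data),))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: ((self, g / self.data),))

    def abs(self):
        return Tensor._make(np.abs(self.data), (self,),
                            lambda g: ((self, g * np.sign(self.data)),))

    def softplus(self):
        """log(1 + exp(x)), numerically stable; gradient is sigmoid(x)."""
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        return Tensor._make(out_data, (self,),
                            lambda g: ((self, g * sigmoid_np(self.data)),))


def sigmoid_np(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def backward(g):
        slabs = np.split(g, len(tensors), axis=axis)
        return tuple((t, np.squeeze(s, axis=axis))
                     for t, s in zip(tensors, slabs))
    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tensors, backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            out.append((t, g[tuple(idx)]))
        return tuple(out)
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def weighted_bce_with_logits(logits: Tensor, targets: np.ndarray,
                             weights: np.ndarray) -> Tensor:
    """Mean of w_i * [softplus(z_i) - z_i * y_i] (stable binary cross-entropy)."""
    y = Tensor(targets)
    w = Tensor(weights)
    per = (logits.softplus() - logits * y) * w
    return per.sum() * (1.0 / logits.data.size)


class Adam:
    """Standard Adam on a flat list of parameter Tensors."""

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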