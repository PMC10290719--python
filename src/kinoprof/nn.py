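"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the attention-based regressor: elementwise
arithmetic with broadcasting, (batched) matrix products, a same-padded 1-D
convolution, softmax, sigmoid/relu, reductions, reshapes and row gathering.
Gradients are accumulated by a topological backward sweep; correctness is
checked against numeric differentiation in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np


def _reduce_to(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff core ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if parent._backward is None and not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- operator sugar ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._backward is not None for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- primitive operations -------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        return ((a, _reduce_to(g, a.shape)), (b, _reduce_to(g, b.shape)))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        return (
            (a, _reduce_to(g * b.data, a.shape)),
            (b, _reduce_to(g * a.data, b.shape)),
        )

    return _make(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return ((a, _reduce_to(ga, a.shape)), (b, _reduce_to(gb, b.shape)))

    return _make(data, (a, b), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        return ((a, g * mask),)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return ((a, g * data * (1.0 - data)),)

    return _make(data, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        return ((a, g * (1.0 - data * data)),)

    return _make(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        return ((a, data * (g - dot)),)

    return _make(data, (a,), backward)


def t_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.shape).copy()),)
        g2 = g
        if not keepdims:
            g2 = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g2, a.shape).copy()),)

    return _make(data, (a,), backward)


def t_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        n = a.data.shape[axis]
    s = t_sum(a, axis=axis, keepdims=keepdims)
    return mul(s, 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        return ((a, g.reshape(a.shape)),)

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        return ((a, g.transpose(inv)),)

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return _make(data, tuple(tensors), backward)


def take_rows(a, indices) -> Tensor:
    """Gather rows along axis 0 (used to share kinase embeddings in a batch)."""
    a = as_tensor(a)
    idx = np.asarray(indices, dtype=np.int64)
    data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return ((a, ga),)

    return _make(data, (a,), backward)


def conv1d_same(x, w, b) -> Tensor:
    """Same-padded stride-1 1-D convolution.

    ``x``: (B, L, C_in); ``w``: (K, C_in, C_out); ``b``: (C_out,).
    Output: (B, L, C_out).
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    B, L, cin = x.shape
    K, _, cout = w.shape
    pad_l = (K - 1) // 2
    pad_r = K - 1 - pad_l
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
    data = np.zeros((B, L, cout), dtype=x.data.dtype)
    for k in range(K):
        data += xp[:, k : k + L, :] @ w.data[k]
    data += b.data

    def backward(g):
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for k in range(K):
            win = xp[:, k : k + L, :]
            gw[k] = np.tensordot(win, g, axes=([0, 1], [0, 1]))
            gxp[:, k : k + L, :] += g @ w.data[k].T
        gx = gxp[:, pad_l : pad_l + L, :]
        gb = g.sum(axis=(0, 1))
        return ((x, gx), (w, gw), (b, gb))

    return _make(data, (x, w, b), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - np.asarray(target, dtype=pred.dtype)
    return t_mean(mul(diff, diff))


# -- parameters and optimiser ----------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
    fan_in = shape[0] if len(shape) == 2 else int(np.prod(shape[:-1]))
    fan_out = shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Adam:
    """Adam optimiser over a list of :class:`Parameter`."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
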