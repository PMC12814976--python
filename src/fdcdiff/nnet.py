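"""Minimal vectorized reverse-mode automatic differentiation and layers.

This module provides the numerical substrate for the equivariant denoiser
and the bond-refinement network: a ``Tensor`` type recording a dynamic
computation graph over float64 NumPy arrays, the handful of primitives the
graph networks need (including row gather and segment-sum for message
passing), ``Linear``/``BatchNorm1d`` layers, SiLU, a fused softmax
cross-entropy, the Adam optimizer, and global-norm gradient clipping.

Gradients are exact reverse-mode derivatives; the test suite checks them
against central finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "silu",
    "softmax_cross_entropy",
    "log_softmax",
    "Linear",
    "BatchNorm1d",
    "MLP",
    "Adam",
    "clip_global_norm",
    "global_grad_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A float64 array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- graph bookkeeping ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic primitives --------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    def square(self):
        def bw(g):
            self._accum(2.0 * self.data * g)

        return self._make(self.data**2, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(0.5 * g / np.maximum(out_data, 1e-300))

        return self._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), bw
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)


def silu(x: Tensor) -> Tensor:
    """SiLU activation x * sigmoid(x)."""
    return x * x.sigmoid()


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad or t._prev for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = bw
    return out


def gather(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]`` (message-passing edge lookup)."""
    index = np.asarray(index, dtype=np.intp)

    def bw(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, index, g)
        x._accum(acc)

    return x._make(x.data[index], (x,), bw)


def segment_sum(x: Tensor, index: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given per-row ids."""
    index = np.asarray(index, dtype=np.intp)
    out_data = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(out_data, index, x.data)

    def bw(g):
        x._accum(g[index])

    return x._make(out_data, (x,), bw)


def log_softmax(x: Tensor) -> Tensor:
    """Row-wise log-softmax, stabilized by a detached max shift."""
    shift = Tensor(x.data.max(axis=1, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=1, keepdims=True).log()


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer class ``targets`` under ``logits``."""
    targets = np.asarray(targets, dtype=np.intp)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(targets)), targets] = 1.0
    return -(Tensor(onehot) * log_softmax(logits)).sum() * (1.0 / len(targets))


# -- layers ---------------------------------------------------------------


class Linear:
    """Dense layer with Kaiming-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(1.0 / n_in)
        self.W = Tensor(
            rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True
        )
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class BatchNorm1d:
    """Batch normalization over rows.

    Normalization always uses the current batch's statistics when it has
    more than one row (running statistics would mix feature scales across
    all diffusion timesteps, which badly miscalibrates the denoiser near
    t = 0); ``training`` only controls whether the running statistics are
    updated.  The accumulated statistics serve single-row batches, where
    batch statistics are undefined.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = (x - mu).square().mean(axis=0, keepdims=True)
            if self.training:
                m = self.momentum
                self.running_mean = (
                    (1 - m) * self.running_mean + m * mu.data[0]
                )
                self.running_var = (
                    (1 - m) * self.running_var + m * var.data[0]
                )
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
            xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class MLP:
    """Stack of Linear layers with SiLU between (and optionally after)."""

    def __init__(
        self,
        dims,
        rng: np.random.Generator,
        final_activation: bool = False,
    ):
        self.layers = [
            Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])
        ]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_activation:
                x = silu(x)
        return x

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


# -- optimization ---------------------------------------------------------


def global_grad_norm(params) -> float:
    """L2 norm of all parameter gradients taken as one vector."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    return float(np.sqrt(total))


def clip_global_norm(params, max_norm: float) -> float:
    """Scale gradients so their global norm is at most ``max_norm``.

    Returns the post-clip global norm.
    """
    norm = global_grad_norm(params)
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
        return max_norm
    return norm


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params, lr=2e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
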