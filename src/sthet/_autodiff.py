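"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind every trainable component in the
package (attention encoders, contrastive objectives, the spot
autoencoder, the communication attention).  It implements exactly the
operations those models need -- elementwise arithmetic with numpy
broadcasting, matrix products, reductions, the activations used by the
model equations (relu / leaky-relu / elu / tanh), exp / log / sqrt,
concatenation and advanced indexing -- as a dynamically built tape that
is walked once, in reverse topological order, by :meth:`Tensor.backward`.

Gradients are dense float64 arrays.  Correctness is established by
central-finite-difference checks in the test suite rather than by
construction, so keep new ops small and obviously local.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _as_data(value) -> Array:
    if isinstance(value, Tensor):
        return value.data
    return np.asarray(value, dtype=np.float64)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[Array], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: Array | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: Array) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_data(other))
        out = Tensor(self.data + o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if o.requires_grad:
                o._accum(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(_as_data(other))))

    def __rsub__(self, other):
        return Tensor(_as_data(other)) + (-self)

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_data(other))
        out = Tensor(self.data * o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * o.data)
            if o.requires_grad:
                o._accum(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_data(other))
        out = Tensor(self.data / o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / o.data)
            if o.requires_grad:
                o._accum(-g * self.data / (o.data ** 2))
        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor(_as_data(other)) / self

    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_data(other))
        out = Tensor(self.data @ o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bwd(g):
            a, b = self.data, o.data
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    self._accum(g * b)
                elif b.ndim == 1:
                    self._accum(np.expand_dims(g, -1) * b)
                elif a.ndim == 1:
                    self._accum(b @ g)
                else:
                    self._accum(g @ b.swapaxes(-1, -2))
            if o.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    o._accum(g * a)
                elif b.ndim == 1:
                    o._accum(np.tensordot(g, a, axes=(tuple(range(g.ndim)),
                                                      tuple(range(g.ndim)))))
                elif a.ndim == 1:
                    o._accum(np.outer(a, g))
                else:
                    o._accum(a.swapaxes(-1, -2) @ g)
        out._backward = bwd
        return out

    def __rmatmul__(self, other):
        return Tensor(_as_data(other)) @ self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out

    # -- shape ops ---------------------------------------------------------
    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.T)
        out._backward = bwd
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bwd
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis] if isinstance(axis, int) else int(
                np.prod([self.data.shape[a] for a in axis]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * val)
        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def sqrt(self) -> "Tensor":
        val = np.sqrt(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * 0.5 / val)
        out._backward = bwd
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - val ** 2))
        out._backward = bwd
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bwd
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data),
                     self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope))
        out._backward = bwd
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        mask = self.data > 0
        expm = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(mask, self.data, expm), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, expm + alpha))
        out._backward = bwd
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        pieces = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(p)
    out._backward = bwd
    return out


def masked_softmax(logits: Tensor, mask: Array, axis: int = -1) -> Tensor:
    """Softmax of ``logits`` restricted to entries where ``mask`` is true.

    Rows with no unmasked entry come out as all-zero rather than NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    fill = np.where(mask, 0.0, -np.inf)
    shifted = logits.data + fill
    row_max = np.max(shifted, axis=axis, keepdims=True, initial=-np.inf)
    row_max = np.where(np.isfinite(row_max), row_max, 0.0)
    # subtract a detached max for stability; gradient flows through logits only
    e = (logits - row_max).exp() * mask.astype(np.float64)
    denom = e.sum(axis=axis, keepdims=True)
    safe = Tensor(np.where(denom.data == 0.0, 1.0, 0.0)) + denom
    return e / safe


def masked_logsumexp(scores: Tensor, mask: Array, axis: int = -1) -> Tensor:
    """log sum_j exp(scores_ij) over the unmasked entries of each row."""
    mask = np.asarray(mask, dtype=bool)
    fill = np.where(mask, 0.0, -np.inf)
    shifted = scores.data + fill
    row_max = np.max(shifted, axis=axis, keepdims=True, initial=-np.inf)
    row_max = np.where(np.isfinite(row_max), row_max, 0.0)
    e = (scores - row_max).exp() * mask.astype(np.float64)
    return e.sum(axis=axis, keepdims=True).log() + row_max


def cosine_similarity_matrix(a: Tensor, b: Tensor, eps: float = 1e-12) -> Tensor:
    """Pairwise cosine similarity between rows of ``a`` and rows of ``b``."""
    na = ((a * a).sum(axis=1, keepdims=True) + eps).sqrt()
    nb = ((b * b).sum(axis=1, keepdims=True) + eps).sqrt()
    return (a @ b.T) / (na @ nb.T)


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> Parameter:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_out, fan_in)
    return Parameter(rng.uniform(-limit, limit, size=shape))


class Adam:
    """Adam optimizer over a flat list of :class:`Parameter`."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class EarlyStopper:
    """Stop when the loss has not improved by ``min_delta`` for ``patience`` epochs."""

    def __init__(self, min_delta: float = 1e-4, patience: int = 10):
        self.min_delta = min_delta
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0

    def update(self, loss: float) -> bool:
        """Record ``loss``; return True when training should stop."""
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss {loss!r}")
        if loss < self.best - self.min_delta:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience
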