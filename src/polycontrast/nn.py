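"""Minimal reverse-mode automatic differentiation and neural-network layers.

This module provides the small numerical engine the rest of the package
trains with: a :class:`Tensor` supporting reverse-mode autodiff over numpy
arrays, the layers needed for a compact transformer encoder and MLP heads
(linear, embedding, layer norm, multi-head self-attention), dropout, the
AdamW optimiser and global gradient-norm clipping.

Everything is float64 and CPU-only. The engine is deliberately small: it
implements exactly the operations the contrastive pre-training objective and
the regression heads require, with broadcasting-aware backward passes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Embedding",
    "MultiHeadSelfAttention",
    "TransformerLayer",
    "FeedForward",
    "dropout",
    "relu",
    "AdamW",
    "clip_grad_norm",
]


#: Training dtype. float32 keeps the desk-scale training loop fast; metric
#: and loss reporting at package boundaries is float64.
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the dimensions numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data, dtype=DTYPE)
        self.data = arr
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction -----------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, parents: tuple["Tensor", ...],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            # copy only views/borrowed buffers; fresh temporaries are adopted
            if grad.base is not None or not grad.flags.owndata:
                grad = grad.copy()
            self.grad = grad
        else:
            self.grad += grad

    # -- basic properties --------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def backward(grad):
            self._accumulate(grad)
            other._accumulate(grad)

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(grad):
            self._accumulate(-grad)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def backward(grad):
            self._accumulate(grad * other.data)
            other._accumulate(grad * self.data)

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward(grad):
            self._accumulate(grad * exponent * self.data ** (exponent - 1.0))

        return Tensor._result(out_data, (self,), backward)

    __pow__ = pow

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def backward(grad):
            self._accumulate(np.matmul(grad, np.swapaxes(other.data, -1, -2)))
            other._accumulate(np.matmul(np.swapaxes(self.data, -1, -2), grad))

        return Tensor._result(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(grad):
            self._accumulate(grad * out_data)

        return Tensor._result(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(grad):
            self._accumulate(grad / self.data)

        return Tensor._result(np.log(self.data), (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0.0

        def backward(grad):
            self._accumulate(grad * mask)

        return Tensor._result(self.data * mask, (self,), backward)

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        old_shape = self.data.shape

        def backward(grad):
            self._accumulate(grad.reshape(old_shape))

        return Tensor._result(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def backward(grad):
            self._accumulate(np.swapaxes(grad, a, b))

        return Tensor._result(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        def backward(grad):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, grad)
            self._accumulate(full)

        return Tensor._result(self.data[idx], (self,), backward)

    # -- graph traversal ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
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
            for parent in node._prev:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def relu(x: Tensor) -> Tensor:
    return x.relu()


def dropout(x: Tensor, p: float, train: bool, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: identity in eval mode or at p == 0."""
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.shape, dtype=DTYPE) >= p).astype(DTYPE)
    mask *= DTYPE(1.0 / (1.0 - p))
    return x * Tensor(mask)


def softmax_last(x: Tensor, bias: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax along the last axis (fused backward).

    ``bias`` is an optional additive constant (e.g. a padding mask) applied
    before normalisation; it carries no gradient.
    """
    z = x.data + bias if bias is not None else x.data
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=-1, keepdims=True)

    def backward(grad):
        inner = (grad * out).sum(axis=-1, keepdims=True)
        x._accumulate(out * (grad - inner))

    return Tensor._result(out, (x,), backward)


def layer_norm(x: Tensor, gamma: "Parameter", beta: "Parameter",
               eps: float = 1e-5) -> Tensor:
    """Last-axis layer normalisation with a fused analytic backward."""
    mu = x.data.mean(axis=-1, keepdims=True)
    centred = x.data - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = centred * inv
    out = xhat * gamma.data + beta.data

    def backward(grad):
        gamma._accumulate(grad * xhat)
        beta._accumulate(grad)
        g = grad * gamma.data
        m1 = g.mean(axis=-1, keepdims=True)
        m2 = (g * xhat).mean(axis=-1, keepdims=True)
        x._accumulate(inv * (g - m1 - xhat * m2))

    return Tensor._result(out, (x, gamma, beta), backward)


def logsumexp_last(x: Tensor) -> Tensor:
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    return (x - shift).exp().sum(axis=-1, keepdims=True).log() + shift


def embedding_lookup(weight: Parameter, ids: np.ndarray) -> Tensor:
    """Gather rows of an embedding table; gradients scatter-add back."""

    def backward(grad):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids, grad)
        weight._accumulate(full)

    return Tensor._result(weight.data[ids], (weight,), backward)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Module:
    """Base class providing parameter iteration and state (de)serialisation."""

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(in_dim)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Embedding(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_rows, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, ids)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention with additive padding mask."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"hidden dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray, attn_dropout: float,
                 train: bool, rng: np.random.Generator) -> Tensor:
        B, L, D = x.shape
        H, Dh = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, Dh).swapaxes(1, 2)  # (B, H, L, Dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(Dh))
        # pad_mask: True where a real token sits; bias -1e9 at padding keys
        bias = np.where(pad_mask[:, None, None, :], DTYPE(0.0), DTYPE(-1e9))
        attn = softmax_last(scores, bias=bias)
        attn = dropout(attn, attn_dropout, train, rng)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, L, D)
        return self.wo(ctx)


class FeedForward(Module):
    def __init__(self, dim: int, ff_dim: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, ff_dim, rng)
        self.fc2 = Linear(ff_dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerLayer(Module):
    """Post-norm transformer block (attention + FFN, residuals, layer norm)."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ffn = FeedForward(dim, ff_dim, rng)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)

    def __call__(self, x: Tensor, pad_mask: np.ndarray, hidden_dropout: float,
                 attn_dropout: float, train: bool, rng: np.random.Generator) -> Tensor:
        a = self.attn(x, pad_mask, attn_dropout, train, rng)
        x = self.ln1(x + dropout(a, hidden_dropout, train, rng))
        f = self.ffn(x)
        return self.ln2(x + dropout(f, hidden_dropout, train, rng))


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(self, params: Iterable[Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def clip_grad_norm(params: Iterable[Parameter], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm.

    Returns the pre-clipping norm.
    """
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm and total > 0.0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total
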