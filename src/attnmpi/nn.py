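"""Reverse-mode automatic differentiation and neural-network layers on numpy.

This module is the numerical substrate for the interaction model: a small
tape-based autograd ``Tensor``, the layers the architecture is built from
(linear maps, layer/batch normalization, dropout, multi-head self-attention,
transformer encoder layers with scalar residual gates) and the Adam optimizer.

Every layer takes an explicit ``numpy.random.Generator`` for parameter
initialization and an explicit ``train`` flag at call time; there is no global
random state and evaluation-mode forward passes are deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "Module",
    "Linear",
    "LayerNorm",
    "BatchNorm1d",
    "Dropout",
    "FeedForward",
    "MultiHeadSelfAttention",
    "TransformerLayer",
    "GatedResidual",
    "Adam",
    "bce_with_logits",
    "softmax_cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array with a gradient tape.

    Operations between tensors (and plain arrays/scalars, which are treated
    as constants) build a DAG; ``backward()`` on a scalar-valued tensor
    accumulates gradients into every ancestor with ``requires_grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward
        self._grad_owned = False

    # -- graph -------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray) -> None:
        # first contribution is kept by reference; a second contribution
        # allocates, so shared upstream gradient buffers are never mutated
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _binary(self, other, out_data, dself, dother):
        other = Tensor._wrap(other)
        track = self.requires_grad or other.requires_grad or self._parents or other._parents

        def bw(g):
            if dself is not None:
                self._accum(_unbroadcast(dself(g), self.data.shape))
            if dother is not None:
                other._accum(_unbroadcast(dother(g), other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw if track else None)

    def __add__(self, other):
        o = Tensor._wrap(other)
        return self._binary(o, self.data + o.data, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        o = Tensor._wrap(other)
        return self._binary(o, self.data - o.data, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return Tensor._wrap(other).__sub__(self)

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __mul__(self, other):
        o = Tensor._wrap(other)
        return self._binary(o, self.data * o.data,
                            lambda g: g * o.data, lambda g: g * self.data)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor._wrap(other)
        return self._binary(o, self.data / o.data,
                            lambda g: g / o.data,
                            lambda g: -g * self.data / (o.data ** 2))

    def __pow__(self, exponent: float):
        out = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor(out, parents=(self,), backward=bw)

    def __matmul__(self, other):
        o = Tensor._wrap(other)
        out = np.matmul(self.data, o.data)

        def dself(g):
            return np.matmul(g, np.swapaxes(o.data, -1, -2))

        def dother(g):
            return np.matmul(np.swapaxes(self.data, -1, -2), g)

        return self._binary(o, out, dself, dother)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        out = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor(out, parents=(self,), backward=bw)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(out, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def sigmoid(self):
        out = _sigmoid(self.data)

        def bw(g):
            self._accum(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=bw)

    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            self._accum(g * out)

        return Tensor(out, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def softmax(self, axis=-1):
        x = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(x)
        out = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            self._accum(out * (g - dot))

        return Tensor(out, parents=(self,), backward=bw)

    def log_softmax(self, axis=-1):
        x = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
        out = x - lse
        sm = np.exp(out)

        def bw(g):
            self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor(out, parents=(self,), backward=bw)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor(out, parents=tuple(tensors), backward=bw)


# -- losses -----------------------------------------------------------------


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits, computed stably.

    loss_i = max(l, 0) - l*y + log(1 + exp(-|l|));  d/dl = sigmoid(l) - y.
    """
    labels = np.asarray(labels, dtype=logits.data.dtype)
    l = logits.data
    per = np.maximum(l, 0) - l * labels + np.log1p(np.exp(-np.abs(l)))
    out = per.mean()

    def bw(g):
        logits._accum(g * (_sigmoid(l) - labels) / l.size)

    return Tensor(out, parents=(logits,), backward=bw)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy for integer ``targets`` over the last axis of ``logits``."""
    targets = np.asarray(targets)
    onehot = np.zeros(logits.shape, dtype=logits.data.dtype)
    np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
    lsm = logits.log_softmax(axis=-1)
    n = targets.size
    return (lsm * onehot).sum() * (-1.0 / n)


# -- modules -----------------------------------------------------------------


class Module:
    """Base class with explicit parameter/child registration."""

    def __init__(self):
        self._params: list[Tensor] = []
        self._children: list["Module"] = []

    def param(self, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params.append(t)
        return t

    def child(self, module: "Module") -> "Module":
        self._children.append(module)
        return module

    def parameters(self):
        yield from self._params
        for c in self._children:
            yield from c.parameters()

    def modules(self):
        yield self
        for c in self._children:
            yield from c.modules()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        """Parameter arrays in registration order (plus buffers, via override)."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = list(self.parameters())
        if len(arrays) != len(params):
            raise ValueError(f"state mismatch: {len(arrays)} arrays, {len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float64):
        super().__init__()
        k = 1.0 / np.sqrt(n_in)
        self.W = self.param(rng.uniform(-k, k, size=(n_in, n_out)).astype(dtype))
        self.b = self.param(np.zeros(n_out, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out if self.b is None else out + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float64):
        super().__init__()
        self.gamma = self.param(np.ones(dim, dtype=dtype))
        self.beta = self.param(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class BatchNorm1d(Module):
    """Batch normalization over axis 0 with running statistics for eval mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        super().__init__()
        self.gamma = self.param(np.ones(dim, dtype=dtype))
        self.beta = self.param(np.zeros(dim, dtype=dtype))
        self.running_mean = np.zeros(dim, dtype=dtype)
        self.running_var = np.ones(dim, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        if train:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta
        xc = x - self.running_mean
        scale = 1.0 / np.sqrt(self.running_var + self.eps)
        return xc * scale * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws masks from its own rng."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        if not train or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        return x * mask


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng, dropout: float = 0.0,
                 dtype=np.float64):
        super().__init__()
        self.fc1 = self.child(Linear(dim, hidden, rng, dtype=dtype))
        self.fc2 = self.child(Linear(hidden, dim, rng, dtype=dtype))
        self.drop = self.child(Dropout(dropout, rng))

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).relu(), train=train))


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over (batch, positions, features)."""

    def __init__(self, dim: int, n_heads: int, rng, dtype=np.float64):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = self.child(Linear(dim, dim, rng, dtype=dtype))
        self.wk = self.child(Linear(dim, dim, rng, dtype=dtype))
        self.wv = self.child(Linear(dim, dim, rng, dtype=dtype))
        self.wo = self.child(Linear(dim, dim, rng, dtype=dtype))

    def _split(self, x: Tensor, B: int, N: int) -> Tensor:
        return x.reshape(B, N, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        B, N, D = x.shape
        q = self._split(self.wq(x), B, N)
        k = self._split(self.wk(x), B, N)
        v = self._split(self.wv(x), B, N)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        if pad_mask is not None:
            # pad_mask: (B, N) boolean, True where padding; optional (off by default)
            bias = np.where(pad_mask[:, None, None, :], -1e9, 0.0)
            scores = scores + bias.astype(scores.data.dtype)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.wo(out)


class TransformerLayer(Module):
    """Post-norm transformer encoder layer (self-attention + feed-forward)."""

    def __init__(self, dim: int, n_heads: int, ff_hidden: int, rng,
                 dropout: float = 0.0, dtype=np.float64):
        super().__init__()
        self.attn = self.child(MultiHeadSelfAttention(dim, n_heads, rng, dtype=dtype))
        self.ffn = self.child(FeedForward(dim, ff_hidden, rng, dropout, dtype=dtype))
        self.ln1 = self.child(LayerNorm(dim, dtype=dtype))
        self.ln2 = self.child(LayerNorm(dim, dtype=dtype))
        self.drop = self.child(Dropout(dropout, rng))

    def __call__(self, x: Tensor, train: bool = False,
                 pad_mask: np.ndarray | None = None) -> Tensor:
        h = self.ln1(x + self.drop(self.attn(x, pad_mask=pad_mask), train=train))
        return self.ln2(h + self.drop(self.ffn(h, train=train), train=train))


class GatedResidual(Module):
    """Learnable residual connection: out = x + gate * layer(x), gate init 0.

    A zero gate makes the wrapped layer an exact identity, so the encoder
    starts from (and can return to) the plain residue embeddings.
    """

    def __init__(self, layer: Module, dtype=np.float64):
        super().__init__()
        self.layer = self.child(layer)
        self.gate = self.param(np.zeros(1, dtype=dtype))

    def __call__(self, x: Tensor, **kw) -> Tensor:
        return x + self.gate * self.layer(x, **kw)


class Adam:
    """Adam with L2 weight decay folded into the gradient (coupled form)."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
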