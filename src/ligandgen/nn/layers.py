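"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Parameter", "Linear", "Embedding", "LayerNorm",
    "MultiHeadSelfAttention", "TransformerEncoderLayer", "LSTMLayer",
    "softmax", "log_softmax", "cross_entropy_logits",
]

DTYPE = np.float32


def Parameter(data: np.ndarray) -> Tensor:
    t = Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)
    return t


class Module:
    """Minimal parameter container; submodules discovered via attributes."""

    def parameters(self, trainable_only: bool = True) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if ((obj.requires_grad or not trainable_only)
                        and id(obj) not in seen):
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # state io walks every parameter, frozen ones included
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters(trainable_only=False)]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters(trainable_only=False)
        if len(params) != len(arrays):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=p.data.dtype)

    def checksum(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for a in self.state_arrays():
            h.update(np.ascontiguousarray(a, dtype=np.float64).tobytes())
        return h.hexdigest()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, gain: float = 1.0):
        bound = gain * math.sqrt(6.0 / (in_dim + out_dim))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.02):
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_tokens, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(ids, dtype=np.int64))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy_logits(logits: Tensor, targets: np.ndarray,
                         mask: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy from raw logits.

    ``logits``: (..., V); ``targets``: integer array matching leading shape;
    ``mask``: optional 0/1 array — positions with 0 are excluded from the mean.
    """
    ls = log_softmax(logits, axis=-1)
    flat = ls.reshape((-1, logits.shape[-1]))
    t = np.asarray(targets, dtype=np.int64).reshape(-1)
    picked = flat[np.arange(t.size), t]
    if mask is None:
        return -picked.mean()
    m = np.asarray(mask, dtype=flat.dtype).reshape(-1)
    denom = float(m.sum())
    if denom == 0:
        raise ValueError("cross-entropy mask excludes every position")
    return -(picked * Tensor(m)).sum() / denom


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("hidden size must be divisible by number of heads")
        self.n_heads = n_heads
        self.dk = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        B, T, D = x.shape
        H, dk = self.n_heads, self.dk

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape((B, T, H, dk)).transpose((0, 2, 1, 3)).reshape((B * H, T, dk))

        q, k, v = split_heads(self.wq(x)), split_heads(self.wk(x)), split_heads(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dk))
        if pad_mask is not None:
            # pad_mask: (B, T) with 1 on real positions
            bias = np.where(pad_mask[:, None, None, :] > 0, 0.0, -1e9).astype(DTYPE)
            bias = np.broadcast_to(bias, (B, H, T, T)).reshape(B * H, T, T)
            scores = scores + Tensor(bias)
        attn = softmax(scores, axis=-1)
        out = attn @ v
        out = out.reshape((B, H, T, dk)).transpose((0, 2, 1, 3)).reshape((B, T, D))
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Post-norm Transformer block (attention + position-wise FFN)."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.norm2 = LayerNorm(dim)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        x = self.norm1(x + self.attn(x, pad_mask))
        x = self.norm2(x + self.ff2(self.ff1(x).relu()))
        return x


class LSTMLayer(Module):
    """Single-direction LSTM over a full sequence.

    Gate order i, f, g, o in one fused weight matrix; forget-gate bias
    initialised to 1 for stable early training.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        bound = math.sqrt(6.0 / (in_dim + hidden + 4 * hidden))
        self.wx = Parameter(rng.uniform(-bound, bound, size=(in_dim, 4 * hidden)))
        self.wh = Parameter(rng.uniform(-bound, bound, size=(hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = Parameter(b)

    def __call__(self, xs: list[Tensor], reverse: bool = False,
                 h0: Tensor | None = None, c0: Tensor | None = None) -> list[Tensor]:
        """xs: length-T list of (B, D) tensors -> length-T list of (B, H).

        Sequences travel as per-step lists: backward through a step list is
        cheap slicing, whereas slicing a packed (B, T, D) tensor per step
        would scatter into full-size zero arrays every timestep.
        """
        T = len(xs)
        B = xs[0].shape[0]
        H = self.hidden
        h = h0 if h0 is not None else Tensor(np.zeros((B, H), dtype=DTYPE))
        c = c0 if c0 is not None else Tensor(np.zeros((B, H), dtype=DTYPE))
        steps = range(T - 1, -1, -1) if reverse else range(T)
        outs: list[Tensor | None] = [None] * T
        for t in steps:
            h, c = self.step(xs[t] @ self.wx, h, c)
            outs[t] = h
        return outs  # type: ignore[return-value]

    def step(self, xw_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        """One cell update given the precomputed input projection for step t."""
        from .fused import lstm_pointwise
        gates = xw_t + h @ self.wh + self.b
        return lstm_pointwise(gates, c)

    def project_input(self, x_t: Tensor) -> Tensor:
        return x_t @ self.wx
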