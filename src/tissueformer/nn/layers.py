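"""Transformer building blocks on top of the autograd core.

Encoder layers follow the classic post-norm arrangement:
``x = LN(x + Drop(SelfAttn(x)))`` then ``x = LN(x + Drop(FFN(x)))``.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    __slots__ = ("decay",)

    def __init__(self, data, decay=False):
        super().__init__(data, requires_grad=True)
        self.decay = decay  # whether AdamW weight decay applies


class Module:
    """Tiny module system: named parameters, train/eval mode, state dict."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: checkpoint {arr.shape}, model {p.data.shape}"
                )
            p.data = arr.astype(np.float64).copy()


class Linear(Module):
    """Affine layer; fan-in-scaled normal init unless ``init_scale`` is given
    (``init_scale=0.0`` zero-initializes, the usual choice for output heads)."""

    def __init__(
        self, d_in: int, d_out: int, rng: np.random.Generator, init_scale: float | None = None
    ):
        super().__init__()
        std = np.sqrt(1.0 / d_in) if init_scale is None else init_scale
        w = rng.normal(0.0, std, (d_in, d_out)) if std > 0 else np.zeros((d_in, d_out))
        self.weight = Parameter(w, decay=True)
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.weight) + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator, init_scale=0.02):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, init_scale, (n_tokens, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ag.embedding(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gain, self.bias)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"hidden dim {dim} not divisible by {n_heads} heads")
        self.dim, self.n_heads, self.d_head = dim, n_heads, dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, key_padding_mask: np.ndarray | None = None) -> Tensor:
        """``x``: (B, L, D).  ``key_padding_mask``: (B, L) True = masked key."""
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)  # (B, L, 3D)
        qkv = qkv.reshape(B, L, 3, H, dh).swapaxes(1, 3)  # (B, H, 3, L, dh)
        q = _take3(qkv, 0)
        k = _take3(qkv, 1)
        v = _take3(qkv, 2)
        scores = (q @ k.swapaxes(-1, -2)) * Tensor(np.asarray(1.0 / np.sqrt(dh)))
        add_mask = None
        if key_padding_mask is not None:
            add_mask = np.where(key_padding_mask[:, None, None, :], -1e30, 0.0)
        attn = ag.softmax_last(scores, add_mask)
        ctx = attn @ v  # (B, H, L, dh)
        ctx = ctx.swapaxes(1, 2).reshape(B, L, D)
        return self.out(ctx)


def _take3(x: Tensor, which: int) -> Tensor:
    """Select index ``which`` on axis 2 of a (B, H, 3, L, dh) tensor."""
    out = Tensor(x.data[:, :, which], parents=(x,))

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, :, which] = g
            x._accum(gx, owned=True)

    out._backward = backward
    return out


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, activation: str, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self.act = ag.relu if activation == "relu" else ag.gelu

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.act(self.fc1(x)))


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer with configurable activation."""

    def __init__(
        self,
        dim: int,
        n_heads: int,
        activation: str,
        rng: np.random.Generator,
        ffn_mult: int = 4,
        dropout: float = 0.1,
    ):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ffn = FeedForward(dim, ffn_mult * dim, activation, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.p_drop = dropout

    def __call__(
        self,
        x: Tensor,
        key_padding_mask: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        drop_rng = rng if rng is not None else np.random.default_rng(0)
        h = self.attn(x, key_padding_mask)
        h = ag.dropout(h, self.p_drop, drop_rng, self.training)
        x = self.norm1(x + h)
        h = self.ffn(x)
        h = ag.dropout(h, self.p_drop, drop_rng, self.training)
        return self.norm2(x + h)


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Standard fixed sinusoidal positional encoding, shape (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc
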