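"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the transformer stacks need are implemented, with
fused, numerically stable kernels for softmax, layer normalization and
cross-entropy.  Gradients are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph traversal --------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if id(node) in seen:
                continue
            if processed:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g, owned=False):
        # ``owned`` marks a freshly allocated gradient that may be adopted
        # without copying (never a view of another tensor's grad buffer)
        if self.grad is None:
            self.grad = g if owned else g.copy()
        else:
            self.grad += g

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _const(-1.0)))

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def swapaxes(self, a, b):
        return swapaxes(self, a, b)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _const(x):
    return Tensor(np.asarray(x))


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            ga = _unbroadcast(g, a.data.shape)
            a._accum(ga, owned=ga is not g)
        if b.requires_grad:
            gb = _unbroadcast(g, b.data.shape)
            b._accum(gb, owned=gb is not g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape), owned=True)
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape), owned=True)

    return Tensor(out_data, parents=(a, b), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape), owned=True)
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape), owned=True)

    return Tensor(out_data, parents=(a, b), backward=backward)


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    out = Tensor(a.data.reshape(shape), parents=(a,))
    out._backward = lambda g: a.requires_grad and a._accum(g.reshape(orig))
    return out


def swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    out = Tensor(np.swapaxes(a.data, ax1, ax2), parents=(a,))
    out._backward = lambda g: a.requires_grad and a._accum(np.swapaxes(g, ax1, ax2))
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))
    out._backward = lambda g: a.requires_grad and a._accum(g * mask, owned=True)
    return out


_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)


def gelu(a: Tensor) -> Tensor:
    """tanh-approximation GELU (the common transformer variant)."""
    x = a.data
    inner = _SQRT_2_OVER_PI * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    out_data = 0.5 * x * (1.0 + t)

    def backward(g):
        if a.requires_grad:
            dinner = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * x**2)
            da = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            a._accum(g * da, owned=True)

    return Tensor(out_data, parents=(a,), backward=backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gain.data + bias.data

    def backward(g):
        if gain.requires_grad:
            gain._accum(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad:
            bias._accum(_unbroadcast(g, bias.data.shape))
        if x.requires_grad:
            gh = g * gain.data
            n = x.data.shape[-1]
            gx = (
                gh - gh.mean(axis=-1, keepdims=True)
                - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            x._accum(gx, owned=True)

    return Tensor(out_data, parents=(x, gain, bias), backward=backward)


def softmax_last(x: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax along the last axis, with an optional additive mask (0 / -inf)."""
    z = x.data if additive_mask is None else x.data + additive_mask
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            gx = y * (g - (g * y).sum(axis=-1, keepdims=True))
            x._accum(gx, owned=True)

    return Tensor(y, parents=(x,), backward=backward)


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)
    out_data = weight.data[idx]

    def backward(g):
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            np.add.at(gw, idx.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
            weight._accum(gw, owned=True)

    return Tensor(out_data, parents=(weight,), backward=backward)


def mean_axis(x: Tensor, axis: int) -> Tensor:
    n = x.data.shape[axis]
    out = Tensor(x.data.mean(axis=axis), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(np.repeat(np.expand_dims(g / n, axis), n, axis=axis), owned=True)

    out._backward = backward
    return out


def take_first_token(x: Tensor) -> Tensor:
    """``x[:, 0, :]`` — extract the leading (<cls>) position."""
    out = Tensor(x.data[:, 0, :], parents=(x,))

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, 0, :] = g
            x._accum(gx, owned=True)

    out._backward = backward
    return out


def take_positions(x: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Gather ``x[rows, cols, :]`` from a (B, L, D) tensor → (K, D)."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    out = Tensor(x.data[rows, cols, :], parents=(x,))

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, (rows, cols), g)
            x._accum(gx, owned=True)

    out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = rng.random(x.data.shape) >= p
    scale = 1.0 / (1.0 - p)
    out = Tensor(x.data * keep * scale, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * keep * scale, owned=True)
    return out


def cross_entropy(
    logits: Tensor,
    targets: np.ndarray,
    sample_weights: np.ndarray | None = None,
) -> Tensor:
    """Weighted mean cross-entropy; weights normalized by their sum."""
    targets = np.asarray(targets)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    nll = -logp[np.arange(len(targets)), targets]
    if sample_weights is None:
        w = np.ones(len(targets))
    else:
        w = np.asarray(sample_weights, dtype=float)
    wsum = w.sum()
    loss = (w * nll).sum() / wsum

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(len(targets)), targets] -= 1.0
            logits._accum(g * p * (w / wsum)[:, None], owned=True)

    return Tensor(np.asarray(loss), parents=(logits,), backward=backward)
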