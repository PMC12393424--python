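"""AdamW optimizer and the warmup → linear-decay learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied only to parameters flagged ``decay=True``
    (weight matrices); embeddings, LayerNorm gains and biases are exempt.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay and getattr(p, "decay", False):
                update = update + self.weight_decay * p.data
            p.data -= lr * update

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def warmup_linear_decay(total_steps: int, warmup_ratio: float = 0.1):
    """LR multiplier schedule: linear warmup, then linear decay to zero."""
    warmup = max(1, int(round(warmup_ratio * total_steps)))

    def factor(step: int) -> float:
        if step < warmup:
            return (step + 1) / warmup
        if total_steps <= warmup:
            return 1.0
        return max(0.0, (total_steps - step) / (total_steps - warmup))

    return factor
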