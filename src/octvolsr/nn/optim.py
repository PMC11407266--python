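"""Adam optimizer and the multi-step learning-rate decay schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with bias-corrected first/second moments (standard defaults)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def lr_at_epoch(
    initial_lr: float, milestones: list[int], decay_factor: float, epoch: int, epochs: int
) -> float:
    """Learning rate under multi-step decay.

    ``initial_lr * decay_factor ** (#milestones <= epoch)``; with the
    defaults (0.001, milestones 25/75/125/175, factor 0.5) this yields
    0.001 at epoch 0, 0.0005 at epoch 25 and 0.0000625 at epoch 180.
    """
    if not 0 <= epoch < epochs:
        raise ValueError(f"epoch {epoch} outside [0, {epochs})")
    n = sum(1 for m in milestones if m <= epoch)
    return initial_lr * decay_factor**n
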