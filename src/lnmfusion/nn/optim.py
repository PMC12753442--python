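"""Adam optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Adam:
    """Adam with conventional moment defaults and no weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr * (m / bias1)
                       / (np.sqrt(v / bias2) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_annealing_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Learning rate at `epoch` (0-based): decays from base_lr to 0 over
    `total_epochs` with a half-cosine, no restarts."""
    if total_epochs <= 1:
        return base_lr
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / (total_epochs - 1)))
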