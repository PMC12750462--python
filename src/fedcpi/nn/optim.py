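"""Momentum SGD over named parameter tensors."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["SGD"]


class SGD:
    def __init__(self, params: dict[str, Tensor], lr: float = 0.01,
                 momentum: float = 0.9, weight_decay: float = 0.0,
                 clip_norm: float = 5.0):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params = dict(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm   # global-norm gradient clipping; 0 = off
        self._vel = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm:
            sq = sum(float((p.grad ** 2).sum())
                     for p in self.params.values() if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v = self._vel[name]
            v *= self.momentum
            v -= self.lr * g
            p.data = p.data + v
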