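"""Stochastic gradient descent with classical momentum.

The update is v <- mu * v - lr * g; p <- p + v, with an optional global
gradient-norm clip as a numerical safeguard for the large effective step
that a 0.98 momentum coefficient implies.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .layers import Layer


class SGDMomentum:
    def __init__(
        self,
        model: Layer,
        lr: float = 0.002,
        momentum: float = 0.98,
        clip_grad_norm: Optional[float] = None,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.clip_grad_norm = clip_grad_norm
        self._velocity: List[np.ndarray] = [
            np.zeros_like(p) for _, p in model.named_parameters()
        ]

    def step(self) -> None:
        grads = [g for _, g in self.model.named_gradients()]
        if self.clip_grad_norm is not None:
            total = float(np.sqrt(sum(float((g ** 2).sum()) for g in grads)))
            if total > self.clip_grad_norm:
                scale = self.clip_grad_norm / (total + 1e-12)
                for g in grads:
                    g *= scale
        params = [p for _, p in self.model.named_parameters()]
        for p, g, v in zip(params, grads, self._velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v

    def zero_grad(self) -> None:
        self.model.zero_grad()

    def state(self) -> List[np.ndarray]:
        return self._velocity
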