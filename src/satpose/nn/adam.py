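"""Adaptive moment estimation (ADAM) with bias correction.

Per parameter element, with gradient g at step t:

    m_t = b1 * m_{t-1} + (1 - b1) * g
    v_t = b2 * v_{t-1} + (1 - b2) * g^2
    theta -= alpha * (m_t / (1 - b1^t)) / (sqrt(v_t / (1 - b2^t)) + eps)

Defaults follow the online (batch size 1) training recipe: alpha = 1e-4
(smaller than the usual 2e-3 to keep single-sample updates stable),
b1 = 0.9, b2 = 0.999.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        params: list,
        alpha: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
    ) -> None:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.params = params
        self.alpha = alpha
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * (g * g)
            mhat = m / bc1
            vhat = v / bc2
            p -= self.alpha * mhat / (np.sqrt(vhat) + self.epsilon)
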