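"""NAdam (Nesterov-accelerated adaptive moment) optimizer on dicts of arrays."""

from __future__ import annotations

import numpy as np

__all__ = ["NAdam", "clip_global_norm"]


def clip_global_norm(grads: dict, max_norm: float) -> float:
    """Scale all gradients in place so their joint L2 norm <= max_norm.

    Returns the pre-clip norm.
    """
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads.values())))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


class NAdam:
    """Adam with Nesterov momentum (bias-corrected lookahead form).

    Update, per parameter theta with gradient g at step t (1-based):

        m_t = b1 m_{t-1} + (1-b1) g
        v_t = b2 v_{t-1} + (1-b2) g^2
        mhat = b1 m_t / (1 - b1^{t+1}) + (1-b1) g / (1 - b1^t)
        vhat = v_t / (1 - b2^t)
        theta -= lr * mhat / (sqrt(vhat) + eps)
    """

    def __init__(self, lr=1e-2, betas=(0.9, 0.999), eps=1e-8):
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        """Apply one update in place to every key present in `grads`."""
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for key, g in grads.items():
            p = params[key]
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = b1 * m / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
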