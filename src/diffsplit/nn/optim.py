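"""Adam optimizer and the log-linear learning-rate schedule."""

from __future__ import annotations

import numpy as np


def lr_schedule(lr_start: float, lr_end: float, total_steps: int):
    """Log-linear decay from ``lr_start`` to ``lr_end`` over ``total_steps``.

    Only the endpoints are prescribed; the log-linear interior is this
    package's choice (a geometric ramp reaches both endpoints exactly).
    """
    if not (lr_start >= lr_end > 0):
        raise ValueError("need lr_start >= lr_end > 0")

    def lr_at(step: int) -> float:
        if total_steps <= 1:
            return lr_start
        frac = min(max(step / (total_steps - 1), 0.0), 1.0)
        return float(lr_start * (lr_end / lr_start) ** frac)

    return lr_at


class Adam:
    """Standard Adam over a list of (layer, param_name) references."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(lay.params[k]) for lay, k in params]
        self.v = [np.zeros_like(lay.params[k]) for lay, k in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, (lay, k) in enumerate(self.params):
            g = lay.grads[k]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            lay.params[k] = (lay.params[k] - lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                lay.params[k].dtype
            )
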