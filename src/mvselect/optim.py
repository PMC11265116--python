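"""Full-batch Adam and shared optimizer configuration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OptimizerConfig:
    """First-order optimizer settings shared by all three fitting stages.

    ``lr`` is the Adam step size; training runs for at most ``epochs``
    full-batch steps and stops early once the relative loss change over
    ``patience`` consecutive epochs falls below ``tol``.  ``warmup`` epochs
    at the start of stage 1 run with the sparsity penalty switched off:
    a cold start under the full penalty can collapse the reconstruction to
    zero (a saddle of the penalized objective), while a short unpenalized
    phase first aligns the latent code with the data.
    """

    lr: float = 3e-3
    epochs: int = 1500
    tol: float = 1e-6
    patience: int = 50
    warmup: int = 300
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


class Adam:
    """Adaptive-moment estimation over a flat list of parameter arrays.

    Parameters are updated in place; callers keep references to the arrays.
    """

    def __init__(self, params: list[np.ndarray], config: OptimizerConfig):
        self.params = params
        self.cfg = config
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        cfg = self.cfg
        self.t += 1
        b1t = 1.0 - cfg.beta1**self.t
        b2t = 1.0 - cfg.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= cfg.beta1
            m += (1.0 - cfg.beta1) * g
            v *= cfg.beta2
            v += (1.0 - cfg.beta2) * (g * g)
            p -= cfg.lr * (m / b1t) / (np.sqrt(v / b2t) + cfg.eps)


def early_stop(trace: list[float], cfg: OptimizerConfig) -> bool:
    """True once the relative loss change over the last ``patience`` epochs
    drops below ``tol`` (guarding against division by zero)."""
    if len(trace) <= cfg.patience:
        return False
    prev, cur = trace[-cfg.patience - 1], trace[-1]
    denom = max(abs(prev), 1e-12)
    return abs(prev - cur) / denom < cfg.tol
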