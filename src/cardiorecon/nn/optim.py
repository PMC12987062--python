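"""Adam optimizer over Parameter groups with per-group learning rates."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Adam"]


class Adam:
    """Standard bias-corrected Adam.

    ``groups`` maps a learning-rate multiplier to a list of parameters; the
    effective rate for a parameter is ``lr * multiplier``.  A multiplier of 0
    leaves the parameter values untouched, which is how frozen / preserved
    parameter sets are expressed.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 groups: list[tuple[float, list[Parameter]]] | None = None):
        if groups is None:
            groups = [(1.0, list(params))]
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.groups = [(float(m), list(ps)) for m, ps in groups]
        self._state = {}
        for _, ps in self.groups:
            for p in ps:
                self._state[id(p)] = (np.zeros_like(p.value),
                                      np.zeros_like(p.value))
        self.t = 0

    def zero_grad(self) -> None:
        for _, ps in self.groups:
            for p in ps:
                p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for mult, ps in self.groups:
            rate = self.lr * mult
            for p in ps:
                m, v = self._state[id(p)]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad ** 2
                if rate == 0.0:
                    continue
                p.value -= rate * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
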