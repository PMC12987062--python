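"""Training configuration and results shared by the two trainable stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn.losses import LossParts

__all__ = ["TrainConfig", "TrainingResults", "smooth_targets"]


def smooth_targets(target: np.ndarray, smoothing: float) -> np.ndarray:
    """Blend a one-hot field with the uniform distribution over channels."""
    if smoothing == 0.0:
        return target
    c = target.shape[0]
    return ((1.0 - smoothing) * target
            + np.asarray(smoothing / c, dtype=target.dtype))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults follow the study configuration (Adam, lr 1e-4, equal loss
    weights); epoch counts are deliberately left to the caller because the
    sensible number depends on problem scale.
    """

    epochs: int = 100
    lr: float = 1e-4
    lam1: float = 0.5
    lam2: float = 0.5
    eps: float = 1e-5
    seed: int = 0
    shuffle: bool = True
    #: mix this fraction of a uniform distribution into one-hot targets.
    #: Nonzero smoothing keeps the softmax away from saturation, which is
    #: what lets rare structures (vessels) keep receiving gradient on small
    #: problems; 0 disables it.
    label_smoothing: float = 0.0

    def __post_init__(self):
        if self.lam1 <= 0 or self.lam2 <= 0:
            raise ValueError("loss weights must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must lie in [0, 1)")

    def with_(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


@dataclass
class TrainingResults:
    """Loss history and metadata of one training run."""

    stage: str
    config: TrainConfig
    history: list[LossParts] = field(default_factory=list)
    n_cases: int = 0

    @property
    def losses(self) -> np.ndarray:
        return np.array([h.total for h in self.history])

    @property
    def final_loss(self) -> float:
        return self.history[-1].total if self.history else float("nan")

    def summary(self) -> str:
        lines = [
            f"{self.stage} training results",
            "=" * 40,
            f"cases:        {self.n_cases}",
            f"epochs:       {len(self.history)}",
            f"optimizer:    Adam (lr={self.config.lr:g})",
            f"loss weights: l1={self.config.lam1:g}, dice={self.config.lam2:g}",
        ]
        if self.history:
            h0, h1 = self.history[0], self.history[-1]
            lines += [
                f"initial loss: {h0.total:.5f} (l1={h0.l1:.5f}, dice={h0.dice:.5f})",
                f"final loss:   {h1.total:.5f} (l1={h1.l1:.5f}, dice={h1.dice:.5f})",
            ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss-vs-epoch curve (total plus both components)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, len(self.history) + 1)
        ax.plot(epochs, [h.total for h in self.history], label="total")
        ax.plot(epochs, [h.l1 for h in self.history], label="L1", alpha=0.6)
        ax.plot(epochs, [h.dice for h in self.history], label="Dice", alpha=0.6)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.set_title(f"{self.stage} loss history")
        ax.legend()
        return ax
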