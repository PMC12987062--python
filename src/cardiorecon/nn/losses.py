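"""Reconstruction loss: weighted voxel-wise L1 plus multi-class soft Dice.

The L1 term is the mean over voxels of the channel-wise absolute difference;
the Dice term pools intersections and squared norms over all classes and
voxels into a single fraction,

    L_Dice = 1 - 2 * sum_c sum_i P Y / (sum_c sum_i P^2 + sum_c sum_i Y^2 + eps),

with the squared denominator.  Both are differentiable in P, which is all
training needs (targets are one-hot constants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossParts", "combined_loss", "combined_loss_grad"]

DEFAULT_EPS = 1e-5


@dataclass(frozen=True)
class LossParts:
    total: float
    l1: float
    dice: float


def _check(pred: np.ndarray, target: np.ndarray, lam1: float, lam2: float):
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if lam1 <= 0 or lam2 <= 0:
        raise ValueError("loss weights must be positive")


def _parts(pred, target, lam1, lam2, eps):
    n_vox = int(np.prod(pred.shape[1:]))
    l1 = float(np.abs(pred - target).sum() / n_vox)
    inter = float((pred * target).sum())
    denom = float((pred ** 2).sum() + (target ** 2).sum() + eps)
    dice = 1.0 - 2.0 * inter / denom
    return l1, dice, inter, denom, n_vox


def combined_loss(pred: np.ndarray, target: np.ndarray,
                  lam1: float = 0.5, lam2: float = 0.5,
                  eps: float = DEFAULT_EPS) -> LossParts:
    """Evaluate lam1 * L1 + lam2 * Dice on (C, ...) probability tensors."""
    _check(pred, target, lam1, lam2)
    l1, dice, *_ = _parts(pred, target, lam1, lam2, eps)
    return LossParts(total=lam1 * l1 + lam2 * dice, l1=l1, dice=dice)


def combined_loss_grad(pred: np.ndarray, target: np.ndarray,
                       lam1: float = 0.5, lam2: float = 0.5,
                       eps: float = DEFAULT_EPS) -> tuple[LossParts, np.ndarray]:
    """Loss plus its gradient with respect to ``pred``."""
    _check(pred, target, lam1, lam2)
    l1, dice, inter, denom, n_vox = _parts(pred, target, lam1, lam2, eps)
    d_l1 = np.sign(pred - target) / n_vox
    # d/dP of (1 - 2 I / D) with I = sum(P Y), D = sum(P^2) + sum(Y^2) + eps
    d_dice = (-2.0 * target * denom + 2.0 * inter * 2.0 * pred) / denom ** 2
    grad = (lam1 * d_l1 + lam2 * d_dice).astype(pred.dtype)
    return LossParts(total=lam1 * l1 + lam2 * dice, l1=l1, dice=dice), grad
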