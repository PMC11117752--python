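"""Composite segmentation training loss.

Total loss  L = l1*L_Dice + l2*L_CE + l3*L_KL + l3*L_L2  with defaults
l1=1.0, l2=0.1, l3=0.1.  L_CE is voxelwise binary cross entropy reweighted
by a spatial map w(y) = 1 + M (edge or cavity-distance emphasis); L_KL and
L_L2 regularize the variational reconstruction branch.  These are the
reference (pure numpy) definitions; the trainer's autodiff graph mirrors
them term for term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError
from .spatial import WeightMap

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "soft_dice_loss",
    "weighted_cross_entropy",
    "kl_divergence_term",
    "reconstruction_term",
    "total_loss",
    "PROB_CLIP",
]

# probability clip before logs; keeps CE finite for saturated predictions
PROB_CLIP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Term weights; lambda3 multiplies BOTH the KL and the L2 term."""

    lambda1: float = 1.0   # Dice term
    lambda2: float = 0.1   # weighted cross entropy
    lambda3: float = 0.1   # KL and L2 (variational branch)

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValidationError("loss weights must be >= 0")


@dataclass(frozen=True)
class LossBreakdown:
    dice_term: float
    ce_term: float
    kl_term: float
    l2_term: float
    total: float

    def is_finite(self) -> bool:
        return bool(np.isfinite([self.dice_term, self.ce_term, self.kl_term,
                                 self.l2_term, self.total]).all())


def _as_arrays(pred, target):
    p = np.asarray(getattr(pred, "data", pred), dtype=np.float64)
    t = np.asarray(getattr(target, "data", target), dtype=np.float64)
    if p.shape != t.shape:
        raise ValidationError(f"pred/target shape mismatch {p.shape} vs {t.shape}")
    return p, t


def soft_dice_loss(pred, target, eps_num: float = 0.0, eps_den: float = 1e-5) -> float:
    """1 - (2*sum(y*y') + eps_num) / (sum(y^2) + sum(y'^2) + eps_den).

    Training smoothing defaults (0, 1e-5).  Squared sums in the denominator;
    for binary targets sum(y^2) equals the voxel count.  Degenerate case:
    both masks empty gives loss 1.0 (0/eps_den) -- training sets always
    contain lesion voxels, so this is documented rather than special-cased.
    """
    p, t = _as_arrays(pred, target)
    if eps_den <= 0 and (p ** 2).sum() + (t ** 2).sum() <= 0:
        raise ValidationError("zero denominator: eps_den must be > 0 for empty inputs")
    num = 2.0 * float((p * t).sum()) + eps_num
    den = float((p ** 2).sum() + (t ** 2).sum()) + eps_den
    return 1.0 - num / den


def weighted_cross_entropy(pred, target, weights: WeightMap | np.ndarray | None = None) -> float:
    """-(1/N) * sum_i w_i * [y_i log y'_i + (1-y_i) log(1-y'_i)].

    ``weights=None`` means uniform (w == 1), i.e. standard mean binary cross
    entropy.  Predictions are clipped to [1e-7, 1-1e-7] before logs.
    """
    p, t = _as_arrays(pred, target)
    if weights is None:
        w = 1.0
    else:
        w = np.asarray(getattr(weights, "data", weights), dtype=np.float64)
        if w.shape != p.shape:
            raise ValidationError(f"weights shape mismatch {w.shape} vs {p.shape}")
        if w.min() < 1.0 - 1e-12 or w.max() > 2.0 + 1e-12:
            raise ValidationError("weights must lie in [1,2] (w = 1 + M, M in [0,1])")
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    ce = w * (t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
    return float(-np.mean(ce))


def kl_divergence_term(mu, log_var, n_voxels: int) -> float:
    """KL(q(z|x) || N(0,I)) / n_voxels = sum(mu^2 + e^v - v - 1) / n_voxels.

    Normalizing by the image voxel count follows the originating
    architecture's convention; swap ``n_voxels`` for a different
    normalization if desired.
    """
    mu = np.asarray(mu, dtype=np.float64).ravel()
    lv = np.asarray(log_var, dtype=np.float64).ravel()
    if n_voxels < 1:
        raise ValidationError("n_voxels must be >= 1")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))):
        raise ValidationError("non-finite latent statistics")
    return float((mu ** 2 + np.exp(lv) - lv - 1.0).sum() / n_voxels)


def reconstruction_term(recon, original) -> float:
    """Mean squared error between the variational reconstruction and the input."""
    r, x = _as_arrays(recon, original)
    return float(np.mean((r - x) ** 2))


def total_loss(dice_term: float, ce_term: float, kl_term: float, l2_term: float,
               weights: LossWeights = LossWeights()) -> LossBreakdown:
    """Assemble the lambda-weighted composite loss from its four terms."""
    terms = (dice_term, ce_term, kl_term, l2_term)
    if not np.all(np.isfinite(terms)):
        raise ValidationError(f"non-finite loss component in {terms}")
    total = (weights.lambda1 * dice_term + weights.lambda2 * ce_term
             + weights.lambda3 * kl_term + weights.lambda3 * l2_term)
    return LossBreakdown(dice_term, ce_term, kl_term, l2_term, float(total))
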