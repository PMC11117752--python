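"""Per-case evaluation metrics.

Smoothed Dice (evaluation smoothing eps=0.001 so an empty-vs-empty pair
scores 1 instead of penalizing a correct no-lesion prediction), robust
95th-percentile Hausdorff distance in mm over 6-connectivity surface
voxels, voxelwise sensitivity/specificity, and lesion volumes in ml.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ValidationError, require_same_geometry
from .spatial import surface_voxels

__all__ = [
    "CaseMetrics",
    "smoothed_dice",
    "robust_hd95",
    "confusion_rates",
    "evaluate_case",
]


@dataclass
class CaseMetrics:
    case_id: str
    dice: float
    hd95_mm: float
    sensitivity: float
    specificity: float
    true_volume_ml: float
    pred_volume_ml: float
    empty_pred: bool
    empty_truth: bool

    def as_dict(self) -> dict:
        return asdict(self)


def _pair(pred: BinaryMask, truth: BinaryMask):
    require_same_geometry(pred, truth, "pred and truth masks")
    return pred.data, truth.data


def smoothed_dice(pred: BinaryMask, truth: BinaryMask, eps: float = 0.001) -> float:
    """(2|P & T| + eps) / (|P| + |T| + eps); 1.0 when both masks are empty."""
    p, t = _pair(pred, truth)
    inter = float(np.logical_and(p, t).sum())
    return (2.0 * inter + eps) / (float(p.sum()) + float(t.sum()) + eps)


def _directed_p95(from_surface: np.ndarray, to_surface: np.ndarray, spacing) -> float:
    """95th percentile (linear interpolation) of distances from each surface
    voxel of ``from_surface`` to the nearest surface voxel of ``to_surface``."""
    dist_to_target = ndimage.distance_transform_edt(~to_surface, sampling=spacing)
    return float(np.percentile(dist_to_target[from_surface], 95))


def robust_hd95(pred: BinaryMask, truth: BinaryMask, spacing=None) -> tuple[float, bool]:
    """Robust Hausdorff distance: max of the two directed 95th percentiles, mm.

    Surfaces are 6-connectivity face-boundary voxels; distances are
    voxel-center Euclidean under the anisotropic spacing.  Identical masks
    (including both empty) give 0.  When exactly one mask is empty there is
    no surface to compare: the physical diagonal of the volume is returned
    as a finite sentinel and the flag is set so reports can exclude the case.

    Returns ``(hd95_mm, sentinel_used)``.
    """
    p, t = _pair(pred, truth)
    spacing = tuple(spacing) if spacing is not None else pred.spacing
    pe, te = not p.any(), not t.any()
    if pe and te:
        return 0.0, False
    if pe or te:
        extent = np.asarray(p.shape, dtype=float) * np.asarray(spacing)
        return float(np.linalg.norm(extent)), True
    ps, ts = surface_voxels(p), surface_voxels(t)
    return max(_directed_p95(ps, ts, spacing), _directed_p95(ts, ps, spacing)), False


def confusion_rates(pred: BinaryMask, truth: BinaryMask) -> tuple[float, float]:
    """Voxelwise (sensitivity, specificity).

    Empty truth makes sensitivity undefined; by convention it is 1 when the
    prediction is also empty (correct no-lesion call) and 0 otherwise.
    """
    p, t = _pair(pred, truth)
    tp = float(np.logical_and(p, t).sum())
    fn = float(np.logical_and(~p, t).sum())
    tn = float(np.logical_and(~p, ~t).sum())
    fp = float(np.logical_and(p, ~t).sum())
    if tp + fn == 0:
        sens = 1.0 if fp == 0 else 0.0
    else:
        sens = tp / (tp + fn)
    spec = tn / (tn + fp) if tn + fp > 0 else 1.0
    return sens, spec


def evaluate_case(pred: BinaryMask, truth: BinaryMask, spacing=None,
                  case_id: str = "", dice_eps: float = 0.001) -> CaseMetrics:
    """All per-case metrics for one predicted/annotated mask pair."""
    require_same_geometry(pred, truth, "pred and truth masks")
    spacing = tuple(spacing) if spacing is not None else pred.spacing
    hd95, sentinel = robust_hd95(pred, truth, spacing)
    sens, spec = confusion_rates(pred, truth)
    vox_ml = float(np.prod(spacing)) / 1000.0
    return CaseMetrics(
        case_id=case_id,
        dice=smoothed_dice(pred, truth, dice_eps),
        hd95_mm=hd95,
        sensitivity=sens,
        specificity=spec,
        true_volume_ml=float(truth.data.sum()) * vox_ml,
        pred_volume_ml=float(pred.data.sum()) * vox_ml,
        empty_pred=pred.is_empty(),
        empty_truth=truth.is_empty(),
    )
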