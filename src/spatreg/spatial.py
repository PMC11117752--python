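"""Distance fields and spatial loss-weight maps.

The training loss re-weights voxelwise cross entropy by the spatial
relationship of each voxel to either the lesion boundary (edge weighting)
or the resection cavity (cavity-distance weighting).  Both weight maps are
``w = 1 + M`` with ``M`` in [0, 1]; the +1 offset keeps a floor under the
gradient everywhere, so weights are bounded in [1, 2].  Maps are computed
once from the ground-truth masks before training and are never needed at
inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ValidationError, Volume3D, require_same_geometry

__all__ = [
    "DistanceField",
    "WeightMap",
    "surface_voxels",
    "distance_to_set",
    "edge_weight_map",
    "cavity_weight_map",
    "uniform_weight_map",
    "approximate_cavity_mask",
    "EmptyReferenceError",
]

logger = logging.getLogger(__name__)

# 6-connectivity structuring element: face-adjacent neighbors only.  The same
# surface definition is reused by the HD95 metric so loss weighting and
# evaluation agree on what "the boundary" is.
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


class EmptyReferenceError(ValidationError):
    """The reference set (boundary or region) is empty; distances undefined."""


@dataclass
class DistanceField:
    """Per-voxel Euclidean distance in mm to a reference voxel set."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    reference_set: str  # "lesion_boundary" | "cavity" | free-form label

    @property
    def shape(self):
        return self.data.shape


@dataclass
class WeightMap:
    """Loss weight grid ``w = 1 + M``, M in [0,1], so w in [1,2]."""

    data: np.ndarray
    kind: str  # "edge" | "cavity_distance" | "uniform"
    param_mm: float | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.size and (d.min() < 1.0 - 1e-12 or d.max() > 2.0 + 1e-12):
            raise ValidationError(
                f"weight map values must lie in [1,2], got range [{d.min()}, {d.max()}]"
            )
        self.data = np.clip(d, 1.0, 2.0)

    @property
    def shape(self):
        return self.data.shape


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face-adjacent background neighbor.

    Voxels on the array border count as surface (outside the grid is
    treated as background).
    """
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~eroded


def distance_to_set(mask: BinaryMask, mode: str, spacing=None) -> DistanceField:
    """Anisotropic Euclidean distance (mm) to a mask-derived reference set.

    mode="boundary": reference = surface voxels of the mask (zero on the
    surface, positive both inside and outside).  mode="region": reference =
    every mask voxel (zero throughout the mask).
    """
    if mode not in ("boundary", "region"):
        raise ValidationError(f"mode must be 'boundary' or 'region', got {mode!r}")
    spacing = tuple(spacing) if spacing is not None else mask.spacing
    if mask.is_empty():
        raise EmptyReferenceError(f"empty reference: {mask.role} mask has no voxels")
    reference = surface_voxels(mask.data) if mode == "boundary" else mask.data
    # EDT measures voxel-center to voxel-center distance to the nearest
    # reference voxel, honoring anisotropic spacing.
    dist = ndimage.distance_transform_edt(~reference, sampling=spacing)
    label = "lesion_boundary" if mode == "boundary" else mask.role
    return DistanceField(np.asarray(dist, dtype=np.float64), spacing, label)


def edge_weight_map(lesion: BinaryMask, tau_mm: float = 3.0) -> WeightMap:
    """Boundary-emphasis weights ``w = 1 + exp(-d_boundary / tau)``.

    Exactly 2 on lesion-surface voxels, decaying toward 1 with distance on
    both sides of the boundary; ``tau_mm`` sets the e-folding width of the
    emphasized band.
    """
    if tau_mm <= 0:
        raise ValidationError(f"tau_mm must be > 0, got {tau_mm}")
    if lesion.is_empty():
        raise EmptyReferenceError("empty lesion: no boundary to weight")
    d = distance_to_set(lesion, "boundary").data
    return WeightMap(1.0 + np.exp(-d / tau_mm), "edge", tau_mm, lesion.spacing)


def cavity_weight_map(cavity: BinaryMask, d_max_mm: float = 40.0,
                      near: bool = True) -> WeightMap:
    """Cavity-distance weights ``w = 1 + max(0, 1 - d_cavity / d_max)``.

    Weight 2 on cavity voxels, ramping linearly down to 1 at ``d_max_mm``.
    Recurrence concentrates at the resection margin, so the default
    emphasizes voxels NEAR the cavity; ``near=False`` flips the ramp
    (``w = 1 + min(1, d/d_max)``) for the opposite convention.
    """
    if d_max_mm <= 0:
        raise ValidationError(f"d_max_mm must be > 0, got {d_max_mm}")
    if cavity.is_empty():
        raise EmptyReferenceError(
            "empty cavity: no reference region; fall back to uniform weights (w == 1)"
        )
    d = distance_to_set(cavity, "region").data
    m = np.clip(1.0 - d / d_max_mm, 0.0, 1.0)
    if not near:
        m = 1.0 - m
    return WeightMap(1.0 + m, "cavity_distance", d_max_mm, cavity.spacing)


def uniform_weight_map(shape, spacing=(1.0, 1.0, 1.0)) -> WeightMap:
    """The w == 1 map (plain cross entropy); fallback when no cavity exists."""
    return WeightMap(np.ones(shape), "uniform", None, tuple(spacing))


def cavity_weight_map_or_uniform(cavity: BinaryMask | None, shape, spacing,
                                 d_max_mm: float = 40.0) -> WeightMap:
    """Cavity weights, or uniform weights with a warning when no cavity exists."""
    if cavity is None or cavity.is_empty():
        logger.warning("no cavity voxels; falling back to uniform loss weights")
        return uniform_weight_map(shape, spacing)
    return cavity_weight_map(cavity, d_max_mm)


def approximate_cavity_mask(volume: Volume3D, lesion: BinaryMask,
                            intensity_percentile: float = 20.0,
                            dilate_voxels: int = 3) -> BinaryMask:
    """Heuristic resection-cavity detector.

    Inside the lesion bounding box (dilated by ``dilate_voxels``), voxels
    strictly below the given within-box intensity percentile are candidates;
    the largest 6-connected component is returned.  The result may be empty
    (a valid outcome for untreated anatomy).  Cavity regions derived this
    way are intrinsically variable: with heavy noise or a very small cavity
    the largest low-intensity cluster may not be the cavity at all.
    """
    if lesion.is_empty():
        raise ValidationError("approximate_cavity_mask requires a nonempty lesion")
    require_same_geometry(volume, lesion, "volume and lesion")

    idx = np.argwhere(lesion.data)
    lo = np.maximum(idx.min(axis=0) - dilate_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + dilate_voxels + 1, lesion.shape)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    sub = volume.data[box]
    support = sub != 0  # exclude zero background that may enter the box
    if not support.any():
        return BinaryMask(np.zeros(lesion.shape, dtype=bool), volume.spacing, role="cavity")
    thresh = np.percentile(sub[support], intensity_percentile)
    cand = (sub < thresh) & support  # strict: a flat distribution yields none
    out = np.zeros(lesion.shape, dtype=bool)
    if cand.any():
        labels, n = ndimage.label(cand, structure=_FACE_STRUCT)
        if n:
            sizes = ndimage.sum_labels(cand, labels, index=np.arange(1, n + 1))
            out[box] = labels == (int(np.argmax(sizes)) + 1)
    return BinaryMask(out, volume.spacing, role="cavity")
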