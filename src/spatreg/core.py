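"""Core volumetric containers.

A :class:`Volume3D` is a scalar 3D image grid with anisotropic voxel
spacing in mm; a :class:`BinaryMask` is a {0,1} indicator grid aligned to
it (lesion or resection-cavity role).  Both round-trip through NIfTI via
nibabel with the spacing encoded in the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "BinaryMask", "ValidationError"]


class ValidationError(ValueError):
    """Raised when a container or operation argument violates its contract."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be three positive mm values, got {spacing}")
    return spacing


@dataclass
class Volume3D:
    """Scalar 3D image with voxel spacing ``(sx, sy, sz)`` in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def physical_diagonal_mm(self) -> float:
        """Length of the volume's physical diagonal (sentinel for one-empty HD)."""
        extent = np.asarray(self.shape, dtype=float) * np.asarray(self.spacing)
        return float(np.linalg.norm(extent))

    def save(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume3D":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing)


@dataclass
class BinaryMask:
    """Binary indicator grid aligned to a :class:`Volume3D`.

    ``role`` distinguishes the hyperintense lesion annotation from the
    post-surgical resection cavity.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    role: str = "lesion"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValidationError(f"mask must be 3D, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask values must be in {{0,1}}, got {uniq[:5]}")
        self.data = arr.astype(bool)
        self.spacing = _check_spacing(self.spacing)
        if self.role not in ("lesion", "cavity"):
            raise ValidationError(f"unknown mask role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def volume_ml(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_mm3 / 1000.0

    def save(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), str(path))

    @classmethod
    def load(cls, path: str | Path, role: str = "lesion") -> "BinaryMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj) > 0.5, spacing, role=role)


def require_same_geometry(a, b, what: str = "inputs") -> None:
    """Raise unless the two containers share shape and spacing."""
    if a.shape != b.shape:
        raise ValidationError(f"{what} have mismatched shapes {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValidationError(f"{what} have mismatched spacings {a.spacing} vs {b.spacing}")
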