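"""Synthetic single-contrast FLAIR-like phantoms.

Real post-treatment cohorts are private, so the toolkit is exercised on 3D
phantoms that emulate the properties the method targets: a hyperintense
lesion with an irregular border and a faint leading-edge halo outside the
annotation; an optional hypointense resection cavity; a bright skull ring
(volumes are not skull-stripped); and exactly-zero background so
nonzero-intensity normalization is well defined.

Two domain styles stand in for the clinical appearance difference:

* ``newly_diagnosed`` -- a sharp, bright, solid lesion (high contrast,
  narrow halo, no cavity).
* ``post_treatment`` -- a dimmer, textured lesion around a resection
  cavity, with a wider halo and small bright treatment-related
  hyperintensities ("mimics") elsewhere in the tissue that belong to no
  annotation.  Post-treatment appearance therefore has to be learned; a
  model trained only on the newly-diagnosed style selects the mimics and
  misses the dim lesion.

Everything is a pure function of the spec's seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, ValidationError, Volume3D

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_cohort",
    "load_manifest",
    "lesion_core_mask",
    "STYLE_DEFAULTS",
    "MANIFEST_COLUMNS",
]

# Domain-style appearance parameters.  Qualitative stand-ins for the clinical
# appearance gap; the direction (post-treatment dimmer, softer, textured,
# cavitated, with non-lesion mimics) is what the data-mixing and
# transfer-learning experiments rely on.
STYLE_DEFAULTS = {
    "newly_diagnosed": {"boundary_softness": 0.3, "lesion_contrast": 2.4,
                        "lesion_texture": 0.05, "cavity": False, "n_mimics": 0},
    "post_treatment": {"boundary_softness": 0.6, "lesion_contrast": 1.7,
                       "lesion_texture": 0.10, "cavity": True, "n_mimics": 3},
}

MANIFEST_COLUMNS = ["case_id", "image", "lesion", "cavity", "domain", "seed"]

_TISSUE_LEVEL = 1.0
_SKULL_LEVEL = 1.8
_CAVITY_LEVEL = 0.35
_SKULL_WIDTH_MM = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    ``boundary_softness`` is the width in mm of the hyperintense halo that
    decays linearly from the annotation boundary down to tissue level
    outside the mask; ``lesion_contrast`` the core-to-tissue
    intensity ratio; ``lesion_texture`` the relative amplitude of smooth
    multiplicative heterogeneity inside the lesion (treated lesions are a
    mix of recurrent tumor and treatment-induced injury, so the
    post-treatment style is markedly more textured); ``irregularity_mm``
    the amplitude of the smoothed-noise perturbation of the ellipsoidal
    border (0 gives a geometric lesion).

    ``n_mimics`` places small faint hyperintensities away from the lesion
    that are NOT part of the annotation -- treatment-related signal changes
    whose intensity mimics the lesion's leading edge.  They are a
    post-treatment-style feature and the reason distant false positives
    (and hence extreme boundary-distance errors) occur in that domain.
    """

    shape: tuple[int, int, int] = (48, 48, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    domain_style: str = "newly_diagnosed"
    lesion_radius_mm: float = 7.0
    boundary_softness: float = 1.0
    lesion_contrast: float = 2.2
    lesion_texture: float = 0.0
    cavity: bool = False
    cavity_radius_mm: float = 3.5
    n_mimics: int = 0
    mimic_contrast: float = 2.2
    mimic_radius_mm: float = 1.8
    irregularity_mm: float = 1.5
    noise_sd: float = 0.05
    seed: int = 0

    @classmethod
    def for_style(cls, style: str, **overrides) -> "PhantomSpec":
        """Spec with the domain-style appearance defaults applied."""
        if style not in STYLE_DEFAULTS:
            raise ValidationError(f"domain_style must be one of {sorted(STYLE_DEFAULTS)}")
        params = {"domain_style": style} | STYLE_DEFAULTS[style] | overrides
        return cls(**params)

    def validate(self) -> None:
        if self.domain_style not in STYLE_DEFAULTS:
            raise ValidationError(f"domain_style: unknown style {self.domain_style!r}")
        if len(self.shape) != 3 or any(int(d) < 8 for d in self.shape):
            raise ValidationError(f"shape: all dims must be >= 8, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing: must be positive, got {self.spacing}")
        if self.lesion_radius_mm <= 0:
            raise ValidationError("lesion_radius_mm: must be > 0")
        half_min_extent = 0.5 * min(d * s for d, s in zip(self.shape, self.spacing))
        if self.lesion_radius_mm >= half_min_extent:
            raise ValidationError(
                f"lesion_radius_mm: {self.lesion_radius_mm} must be < half the "
                f"smallest physical dimension ({half_min_extent} mm)")
        if self.boundary_softness < 0:
            raise ValidationError("boundary_softness: must be >= 0")
        if self.lesion_contrast <= 0:
            raise ValidationError("lesion_contrast: must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be >= 0")
        if not 0 <= self.lesion_texture < 1:
            raise ValidationError("lesion_texture: must be in [0, 1)")
        if self.n_mimics < 0:
            raise ValidationError("n_mimics: must be >= 0")
        if self.n_mimics and (self.mimic_contrast <= 1.0 or self.mimic_radius_mm <= 0):
            raise ValidationError(
                "mimic_contrast must be > 1 and mimic_radius_mm > 0 when n_mimics > 0")
        if self.cavity and self.cavity_radius_mm <= 0:
            raise ValidationError("cavity_radius_mm: must be > 0 when cavity is on")
        if self.domain_style == "post_treatment":
            if not self.cavity:
                raise ValidationError("cavity: post_treatment style requires a cavity")
            if self.boundary_softness < STYLE_DEFAULTS["newly_diagnosed"]["boundary_softness"]:
                raise ValidationError(
                    "boundary_softness: post_treatment ramp must be at least the "
                    "newly_diagnosed default")


def _coords_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _signed_distance_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Positive inside the mask (distance to outside), negative outside."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return inside - outside


def lesion_core_mask(lesion: BinaryMask, boundary_softness: float = 0.0) -> np.ndarray:
    """Voxels carrying the full lesion contrast.

    The annotated lesion is an intensity plateau whose hyperintense halo
    ramps down OUTSIDE the mask over ``boundary_softness`` mm, so every mask
    voxel is core.
    """
    return lesion.data.copy()


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, BinaryMask, BinaryMask]:
    """One synthetic case: (image, lesion mask, cavity mask).

    The cavity mask is empty (all zeros) when the spec has no cavity.
    Deterministic in ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, spacing = tuple(int(d) for d in spec.shape), tuple(spec.spacing)
    xx, yy, zz = _coords_mm(shape, spacing)
    extent = np.asarray(shape, dtype=float) * np.asarray(spacing)
    center = (np.asarray(shape, dtype=float) - 1) / 2.0 * np.asarray(spacing)

    # Head: ellipsoidal tissue region with a fixed-width bright skull shell.
    tissue_axes = 0.42 * extent - _SKULL_WIDTH_MM
    rho = np.sqrt(((xx - center[0]) / tissue_axes[0]) ** 2
                  + ((yy - center[1]) / tissue_axes[1]) ** 2
                  + ((zz - center[2]) / tissue_axes[2]) ** 2)
    tissue = rho <= 1.0
    d_out = ndimage.distance_transform_edt(~tissue, sampling=spacing)
    skull = (d_out > 0) & (d_out <= _SKULL_WIDTH_MM)
    head = tissue | skull

    # Lesion: perturbed ellipsoid via an implicit surface.  The smoothed-noise
    # term bends the border into an irregular, non-geometric shape.
    margin = spec.lesion_radius_mm + spec.irregularity_mm + 1.0
    max_off = np.maximum(tissue_axes - margin, 0.0) * 0.35
    lesion_center = center + rng.uniform(-1.0, 1.0, size=3) * max_off
    aniso = rng.uniform(0.85, 1.2, size=3)
    r_mm = np.sqrt((((xx - lesion_center[0]) * aniso[0]) ** 2)
                   + (((yy - lesion_center[1]) * aniso[1]) ** 2)
                   + (((zz - lesion_center[2]) * aniso[2]) ** 2))
    phi = r_mm - spec.lesion_radius_mm
    if spec.irregularity_mm > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.5)
        sd = noise.std()
        if sd > 0:
            phi = phi + spec.irregularity_mm * (noise / sd)
    # keep the lesion strictly inside tissue, away from the skull
    interior = _signed_distance_mm(tissue, spacing) > 1.5
    lesion_region = (phi < 0) & interior
    if lesion_region.any():  # largest connected component only
        labels, n = ndimage.label(lesion_region)
        sizes = ndimage.sum_labels(lesion_region, labels, index=np.arange(1, n + 1))
        lesion_region = labels == (int(np.argmax(sizes)) + 1)
    else:  # degenerate spec (tiny grid): fall back to the unperturbed ellipsoid
        lesion_region = (r_mm <= spec.lesion_radius_mm) & interior
        if not lesion_region.any():
            raise ValidationError("lesion_radius_mm: lesion does not fit inside the tissue")

    # Cavity: a sphere near the lesion center, hypointense.
    cavity_region = np.zeros(shape, dtype=bool)
    if spec.cavity:
        cav_center = lesion_center + rng.uniform(-1.0, 1.0, size=3) * 0.1 * spec.lesion_radius_mm
        rc = np.sqrt((xx - cav_center[0]) ** 2 + (yy - cav_center[1]) ** 2
                     + (zz - cav_center[2]) ** 2)
        cavity_region = (rc <= spec.cavity_radius_mm) & interior

    hyper = lesion_region & ~cavity_region  # the annotated T2-hyperintense lesion

    # Intensities: the annotated lesion is a full-contrast plateau; outside
    # it, hyperintensity decays linearly to tissue level over
    # boundary_softness mm -- the faint leading edge beyond the annotation
    # that makes the post-treatment boundary hard to place.
    img = np.zeros(shape, dtype=np.float64)
    img[tissue] = _TISSUE_LEVEL
    img[skull] = _SKULL_LEVEL
    s = _signed_distance_mm(hyper, spacing)
    if spec.boundary_softness > 0:
        ramp = np.clip(1.0 + s / spec.boundary_softness, 0.0, 1.0)
    else:
        ramp = hyper.astype(np.float64)
    boost = (spec.lesion_contrast - 1.0) * _TISSUE_LEVEL * ramp
    if spec.lesion_texture > 0:
        # smooth multiplicative heterogeneity of the hyperintense signal
        tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        sd = tex.std()
        if sd > 0:
            boost = boost * np.clip(1.0 + spec.lesion_texture * tex / sd, 0.0, None)
    img[tissue] += boost[tissue]
    if cavity_region.any():
        img[cavity_region] = _CAVITY_LEVEL

    # Faint non-lesion hyperintensities (treatment-related signal change):
    # small soft-edged blobs away from the lesion, at leading-edge-like
    # intensity, excluded from every mask.
    if spec.n_mimics:
        d_lesion = ndimage.distance_transform_edt(~lesion_region, sampling=spacing)
        tissue_depth = _signed_distance_mm(tissue, spacing)
        ok = (tissue_depth > spec.mimic_radius_mm + 1.0) & \
             (d_lesion > spec.boundary_softness + spec.mimic_radius_mm + 2.0)
        sites = np.argwhere(ok)
        if sites.size:
            placed = 0
            for _ in range(20 * spec.n_mimics):
                if placed == spec.n_mimics:
                    break
                c_vox = sites[rng.integers(0, len(sites))]
                c_mm = c_vox * np.asarray(spacing, dtype=float)
                rm = np.sqrt((xx - c_mm[0]) ** 2 + (yy - c_mm[1]) ** 2 + (zz - c_mm[2]) ** 2)
                blob = np.clip((spec.mimic_radius_mm + 1.5 - rm) / 1.5, 0.0, 1.0)
                img[tissue] += (spec.mimic_contrast - 1.0) * _TISSUE_LEVEL * blob[tissue]
                placed += 1

    if spec.noise_sd > 0:
        img[head] += rng.normal(0.0, spec.noise_sd, size=int(head.sum()))

    return (
        Volume3D(img, spacing),
        BinaryMask(hyper, spacing, role="lesion"),
        BinaryMask(cavity_region, spacing, role="cavity"),
    )


def _case_seed(cohort_seed: int, index: int) -> int:
    return int(np.random.SeedSequence(cohort_seed, spawn_key=(index,)).generate_state(1)[0]
               % (2 ** 31))


def generate_cohort(n_pre: int, n_post: int, base_spec: PhantomSpec, seed: int,
                    out_dir: str | Path) -> pd.DataFrame:
    """Write ``n_pre`` newly-diagnosed and ``n_post`` post-treatment cases.

    Each case gets a seed derived from the cohort seed, NIfTI image/mask
    files, and a manifest row; returns the manifest (also saved as
    ``manifest.csv`` in ``out_dir``).
    """
    if n_pre + n_post < 1:
        raise ValidationError("cohort must contain at least one case")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    overrides = dataclasses.asdict(base_spec)
    for k in ("domain_style", "boundary_softness", "lesion_contrast",
              "lesion_texture", "cavity", "n_mimics", "seed"):
        overrides.pop(k)
    overrides["shape"] = tuple(overrides["shape"])
    overrides["spacing"] = tuple(overrides["spacing"])

    rows = []
    styles = ["newly_diagnosed"] * n_pre + ["post_treatment"] * n_post
    for i, style in enumerate(styles):
        case_id = f"case_{i:04d}"
        spec = PhantomSpec.for_style(style, seed=_case_seed(seed, i), **overrides)
        vol, lesion, cavity = generate_phantom(spec)
        image_path = out_dir / f"{case_id}_image.nii.gz"
        lesion_path = out_dir / f"{case_id}_lesion.nii.gz"
        vol.save(image_path)
        lesion.save(lesion_path)
        cavity_path = ""
        if not cavity.is_empty():
            cavity_path = str(out_dir / f"{case_id}_cavity.nii.gz")
            cavity.save(cavity_path)
        rows.append({"case_id": case_id, "image": str(image_path),
                     "lesion": str(lesion_path), "cavity": cavity_path,
                     "domain": style, "seed": spec.seed})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns {missing}")
    if manifest["case_id"].duplicated().any():
        raise ValidationError("manifest case_ids are not unique")
    return manifest
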