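"""Multivariate signature scoring of beta images.

The signature response of an activation image is the dot product of the
vectorized image with the signature's voxel weights over the signature mask.
Local responses restrict the sum to labelled sub-regions; sphere-ROI
averages pool raw beta values around a world-space center.  No resampling is
ever performed: images must share the signature's grid exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "SignaturePattern",
    "PatternResponse",
    "pattern_response",
    "local_pattern_response",
    "roi_sphere_average",
]


def _as_volume(image):
    """Accept a 3-D ndarray or a nibabel image; return (data, affine|None)."""
    if isinstance(image, nib.spatialimages.SpatialImage):
        return np.asarray(image.get_fdata()), image.affine
    return np.asarray(image, dtype=float), None


@dataclass
class SignaturePattern:
    """Voxel weight map with support mask and optional sub-region labels.

    Vectorization is Fortran-order over the grid (ascending linear index,
    slowest-varying axis last), applied identically to weights and images so
    serialized vectors are reproducible; the dot product itself is
    order-invariant.
    """

    weights: np.ndarray          # 3-D, defined on mask voxels (0 elsewhere)
    mask: np.ndarray             # 3-D bool
    affine: np.ndarray
    region_labels: np.ndarray | None = None  # 3-D int, nonzero subset of mask

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.weights.shape != self.mask.shape:
            raise ValueError("weights and mask shapes differ")
        if self.region_labels is not None:
            if self.region_labels.shape != self.mask.shape:
                raise ValueError("region_labels shape differs from mask")
            if ((self.region_labels != 0) & ~self.mask).any():
                raise ValueError("region labels extend outside the mask")

    @property
    def weight_vector(self) -> np.ndarray:
        """Weights at mask voxels in the fixed (Fortran) vectorization order."""
        return self.weights.ravel(order="F")[self.mask.ravel(order="F")]

    def region_ids(self) -> list:
        if self.region_labels is None:
            return []
        ids = np.unique(self.region_labels)
        return [int(i) for i in ids if i != 0]

    # -- NIfTI round trip -------------------------------------------------
    def to_nifti(self):
        return (
            nib.Nifti1Image(self.weights.astype(np.float64), self.affine),
            nib.Nifti1Image(self.mask.astype(np.uint8), self.affine),
            None if self.region_labels is None
            else nib.Nifti1Image(self.region_labels.astype(np.int16), self.affine),
        )

    @classmethod
    def from_nifti(cls, weights_img, mask_img=None, regions_img=None):
        w = nib.load(weights_img) if isinstance(weights_img, str) else weights_img
        weights = np.asarray(w.get_fdata())
        if mask_img is None:
            mask = weights != 0
        else:
            m = nib.load(mask_img) if isinstance(mask_img, str) else mask_img
            mask = np.asarray(m.get_fdata()) > 0
        regions = None
        if regions_img is not None:
            r = nib.load(regions_img) if isinstance(regions_img, str) else regions_img
            regions = np.asarray(r.get_fdata()).astype(int)
        return cls(weights=weights, mask=mask, affine=w.affine, region_labels=regions)


@dataclass
class PatternResponse:
    value: float
    scope: str = "whole"   # "whole" or "region:<id>"
    trial: object = None
    n_missing: int = 0     # in-mask voxels absent (NaN) in the image


def _masked_dot(beta, weights, vox_mask, scope, trial):
    vals = beta[vox_mask]
    w = weights[vox_mask]
    missing = ~np.isfinite(vals)
    n_missing = int(missing.sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} in-mask voxels missing from image; contributing 0"
        )
        vals = np.where(missing, 0.0, vals)
    return PatternResponse(
        value=float(np.dot(w, vals)), scope=scope, trial=trial, n_missing=n_missing
    )


def pattern_response(beta_volume, signature: SignaturePattern, trial=None) -> PatternResponse:
    """Whole-pattern dot product of a beta image with the signature weights."""
    beta, affine = _as_volume(beta_volume)
    if beta.shape != signature.mask.shape:
        raise ValueError(
            f"grid mismatch: image {beta.shape} vs signature {signature.mask.shape}"
        )
    if affine is not None and not np.allclose(affine, signature.affine, atol=1e-6):
        raise ValueError("affine mismatch between image and signature (no resampling)")
    return _masked_dot(beta, signature.weights, signature.mask, "whole", trial)


def local_pattern_response(
    beta_volume, signature: SignaturePattern, region_id: int, trial=None
) -> PatternResponse:
    """Dot product restricted to one labelled sub-region of the signature."""
    if signature.region_labels is None:
        raise ValueError("signature has no region labels")
    vox = signature.region_labels == region_id
    if not vox.any():
        raise ValueError(f"region {region_id} is empty")
    beta, affine = _as_volume(beta_volume)
    if beta.shape != signature.mask.shape:
        raise ValueError("grid mismatch between image and signature")
    if affine is not None and not np.allclose(affine, signature.affine, atol=1e-6):
        raise ValueError("affine mismatch between image and signature")
    return _masked_dot(beta, signature.weights, vox, f"region:{region_id}", trial)


def roi_sphere_average(beta_volume, center_mm, radius_mm: float, affine=None) -> float:
    """Unweighted mean of beta values in a sphere around a world coordinate.

    A voxel is included iff the world position of its center lies within
    ``radius_mm`` (inclusive) of ``center_mm``.
    """
    beta, img_affine = _as_volume(beta_volume)
    affine = img_affine if affine is None else np.asarray(affine)
    if affine is None:
        raise ValueError("an affine is required to map world coordinates")
    shape = beta.shape
    # voxel centers in world space
    idx = np.indices(shape).reshape(3, -1)
    homog = np.vstack([idx, np.ones(idx.shape[1])])
    world = (affine @ homog)[:3]
    d2 = np.sum((world - np.asarray(center_mm, dtype=float)[:, None]) ** 2, axis=0)
    inside = d2 <= radius_mm**2
    if not inside.any():
        raise ValueError("sphere contains no voxel centers")
    return float(beta.reshape(-1)[inside].mean())
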