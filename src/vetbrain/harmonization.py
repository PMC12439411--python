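"""Scanner-bias reduction on single volumes.

Two steps, applied in this order at test time: N4 bias-field correction
(shrink factor 10, fitting mask at the 60th percentile of foreground
intensity), then per-case z-score normalization.  N4 estimates a smooth,
strictly positive multiplicative field on a downsampled copy of the image
and divides it out; z-scoring maps the whole volume through the affine
transform that gives the foreground mean 0 and standard deviation 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .errors import DegenerateInputError
from .geometry import ImageVolume, foreground_mask, voxel_spacing

__all__ = ["BiasCorrectionParams", "bias_correct", "zscore", "harmonize"]


@dataclass
class BiasCorrectionParams:
    """Knobs of the N4 fit.

    shrink_factor : downsampling applied before fitting the field (>= 1).
    mask_percentile : the fit uses only voxels at or above this percentile
        of the foreground intensity distribution, in (0, 100).
    max_iterations : per-resolution-level iteration cap.
    convergence_tol : stopping tolerance on the field update.
    """

    shrink_factor: int = 10
    mask_percentile: float = 60.0
    max_iterations: int = 50
    convergence_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.shrink_factor < 1:
            raise ValueError("shrink_factor must be >= 1")
        if not 0.0 < self.mask_percentile < 100.0:
            raise ValueError("mask_percentile must be in (0, 100)")


def bias_correct(vol: ImageVolume, params: BiasCorrectionParams | None = None) -> ImageVolume:
    """Divide out a smooth multiplicative intensity field estimated by N4.

    The field is fitted on the image shrunk by ``params.shrink_factor``
    within the mask of voxels at or above the ``mask_percentile`` of
    foreground intensity, then expanded to full resolution; the output is
    the input divided by that strictly positive field, so nonnegative
    intensities stay nonnegative.
    """
    params = params or BiasCorrectionParams()
    fg = foreground_mask(vol.voxels)
    fg_vals = vol.voxels[fg]
    if fg_vals.size == 0:
        raise DegenerateInputError("no foreground voxels to estimate a bias field from")
    thr = float(np.percentile(fg_vals, params.mask_percentile))
    mask = (vol.voxels >= thr) & fg
    if not mask.any():
        raise DegenerateInputError(
            f"empty N4 mask at the {params.mask_percentile}th percentile"
        )

    spacing = voxel_spacing(vol.affine)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.T, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing))
    msk = sitk.GetImageFromArray(np.ascontiguousarray(mask.T.astype(np.uint8)))
    msk.SetSpacing(img.GetSpacing())

    shrink = [max(1, min(params.shrink_factor, n // 2)) for n in img.GetSize()]
    small = sitk.Shrink(img, shrink)
    small_mask = sitk.Shrink(msk, shrink)

    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations([int(params.max_iterations)] * 4)
    n4.SetConvergenceThreshold(float(params.convergence_tol))
    n4.Execute(small, small_mask)
    log_field = n4.GetLogBiasFieldAsImage(img)
    field = np.exp(sitk.GetArrayFromImage(log_field)).T
    corrected = vol.voxels / field
    return ImageVolume(corrected.astype(np.float32), vol.affine, vol.modality_tag)


def zscore(vol: ImageVolume) -> ImageVolume:
    """Standardize foreground intensities to mean 0, standard deviation 1.

    Statistics are computed over the foreground (everything except the
    constant background value); the background is mapped through the same
    affine transform, which makes repeated z-scoring an exact no-op.
    """
    fg = foreground_mask(vol.voxels)
    vals = vol.voxels[fg].astype(np.float64)
    sd = float(vals.std())
    if sd <= 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("zero foreground variance: cannot z-score")
    mean = float(vals.mean())
    out = (vol.voxels.astype(np.float64) - mean) / sd
    return ImageVolume(out.astype(np.float64), vol.affine, vol.modality_tag)


def harmonize(vol: ImageVolume, params: BiasCorrectionParams | None = None) -> ImageVolume:
    """The test-time harmonization: bias correction first, then z-score."""
    return zscore(bias_correct(vol, params))
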