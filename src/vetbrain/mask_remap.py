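"""Map canonical-space masks back to original slice geometry and across modalities.

The reconstruction stores each plane's original affine and shape;
``map_to_original`` realigns a canonical-space prediction to those
original slices by nearest-neighbour resampling.  ``transfer_to_modality``
moves a mask onto another acquisition's grid through both affines,
clipping whatever falls outside the target field of view, and warns when
most of the mask misses the target (the symptom of a patient repositioned
between acquisitions; such cases are flagged, not re-registered).
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import RepositioningWarning
from .geometry import BrainMask, ImageVolume, resample_mask_to_grid

__all__ = ["map_to_original", "transfer_to_modality", "in_fov_fraction"]


def map_to_original(
    mask: BrainMask, original_affine: np.ndarray, original_shape: tuple[int, int, int]
) -> BrainMask:
    """Resample a canonical-grid mask onto the original plane grid (nearest)."""
    return resample_mask_to_grid(mask, np.asarray(original_affine, float), tuple(original_shape))


def in_fov_fraction(mask: BrainMask, target_affine: np.ndarray, target_shape) -> float:
    """Fraction of mask voxels whose world position lands inside the target FOV."""
    if mask.count() == 0:
        return 0.0
    idx = np.argwhere(mask.voxels > 0).astype(float)
    world = idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    m = np.linalg.inv(np.asarray(target_affine, float))
    tgt_idx = world @ m[:3, :3].T + m[:3, 3]
    shape = np.asarray(target_shape, float)
    inside = np.all((tgt_idx >= -0.5) & (tgt_idx <= shape - 0.5), axis=1)
    return float(inside.mean())


def transfer_to_modality(mask: BrainMask, target: ImageVolume) -> BrainMask:
    """Resample a mask into another modality's grid, clipping to its FOV.

    Nearest-neighbour through both affines; mask voxels mapping outside
    the target grid are dropped.  A :class:`RepositioningWarning` is
    emitted when fewer than half of the mask voxels land inside the
    target field of view.
    """
    if min(target.shape) < 2:
        raise ValueError("degenerate target grid")
    fraction = in_fov_fraction(mask, target.affine, target.shape)
    if fraction < 0.5:
        warnings.warn(
            f"only {fraction:.0%} of the mask lands inside the target field of view; "
            "the subject may have been repositioned between acquisitions",
            RepositioningWarning,
        )
    return resample_mask_to_grid(mask, target.affine, target.shape)
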