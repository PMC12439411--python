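"""Voxel-grid / affine arithmetic on 3D image volumes.

The world frame is RAS+ millimetres throughout: the 4x4 ``affine`` of a
volume maps voxel index ``(i, j, k, 1)`` to the world position of that
voxel's *center* (NIfTI convention).  "LAS orientation" means the voxel
axes increase toward the patient's Left, Anterior and Superior — i.e. the
axis codes of the affine are ``('L', 'A', 'S')`` over the RAS world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError

__all__ = [
    "ImageVolume",
    "BrainMask",
    "reorient_to_las",
    "crop_foreground",
    "resample_to_iso_cube",
    "resample_to_grid",
    "world_centroid",
    "voxel_spacing",
    "load_nifti",
    "save_nifti",
    "load_mask",
    "foreground_mask",
]

LAS = ("L", "A", "S")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine upper-left 3x3 block is singular")
    return affine


@dataclass
class ImageVolume:
    """A 3D intensity grid with a voxel-to-world (RAS+ mm) affine.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Real-valued intensities.
    affine : ndarray, shape (4, 4)
        Maps voxel index (homogeneous) to world millimetres; the upper-left
        3x3 block must be invertible.
    modality_tag : str
        Free-text acquisition label (T1, T1ce, T2, T2-FLAIR...).
    """

    voxels: np.ndarray
    affine: np.ndarray
    modality_tag: str = "T1ce"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"voxels must be 3D with positive extents, got shape {self.voxels.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing(self) -> np.ndarray:
        return voxel_spacing(self.affine)

    @property
    def axcodes(self) -> tuple[str, str, str]:
        return nib.aff2axcodes(self.affine)

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to (N, 3) world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class BrainMask:
    """A binary {0,1} grid sharing the affine conventions of :class:`ImageVolume`."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"mask must be 3D with positive extents, got shape {vox.shape}")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be strictly binary (0/1)")
        self.voxels = vox.astype(np.uint8)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


def voxel_spacing(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the 3x3 block)."""
    return np.linalg.norm(np.asarray(affine, float)[:3, :3], axis=0)


def reorient_to_las(vol: ImageVolume) -> ImageVolume:
    """Permute/flip voxel axes so the affine's axis codes become (L, A, S).

    World positions of all voxels are unchanged; only the index frame moves.
    Oblique affines are snapped to the nearest canonical axes (nibabel's
    ``io_orientation``); singular affines are rejected at construction.
    """
    current = nib.orientations.io_orientation(vol.affine)
    target = nib.orientations.axcodes2ornt(LAS)
    xform = nib.orientations.ornt_transform(current, target)
    data = nib.orientations.apply_orientation(vol.voxels, xform)
    affine = vol.affine @ nib.orientations.inv_ornt_aff(xform, vol.voxels.shape)
    return ImageVolume(data, affine, vol.modality_tag)


def crop_foreground(
    vol: ImageVolume, threshold: float
) -> tuple[ImageVolume, tuple[int, int, int]]:
    """Crop to the tight bounding box of voxels with intensity > threshold.

    Returns the cropped volume and the (i, j, k) offset of its first voxel
    in the input index frame.  The affine origin is shifted so every
    retained voxel keeps its world position.
    """
    fg = vol.voxels > threshold
    if not fg.any():
        raise DegenerateInputError(f"no voxel exceeds threshold {threshold!r}")
    lo, hi = [], []
    for ax in range(3):
        proj = fg.any(axis=tuple(a for a in range(3) if a != ax))
        nz = np.flatnonzero(proj)
        lo.append(int(nz[0]))
        hi.append(int(nz[-1]) + 1)
    cropped = vol.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    affine = vol.affine.copy()
    affine[:3, 3] = vol.affine[:3, :3] @ lo + vol.affine[:3, 3]
    return ImageVolume(cropped, affine, vol.modality_tag), (lo[0], lo[1], lo[2])


def resample_to_grid(
    vol: ImageVolume,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    order: int = 1,
    cval: float = 0.0,
) -> ImageVolume:
    """Resample onto an arbitrary target grid by pulling through both affines."""
    target_affine = _check_affine(target_affine)
    # voxel->voxel map: src_idx = inv(src_aff) @ tgt_aff @ tgt_idx
    m = np.linalg.inv(vol.affine) @ target_affine
    idx = np.indices(target_shape, dtype=np.float32).reshape(3, -1)
    src = m[:3, :3].astype(np.float32) @ idx + m[:3, 3:4].astype(np.float32)
    out = ndimage.map_coordinates(
        vol.voxels.astype(np.float32, copy=False), src, order=order, mode="constant", cval=cval
    ).reshape(target_shape)
    return ImageVolume(out, target_affine, vol.modality_tag)


def resample_mask_to_grid(
    mask: BrainMask, target_affine: np.ndarray, target_shape: tuple[int, int, int]
) -> BrainMask:
    """Nearest-neighbour mask resampling; output stays strictly binary."""
    vol = ImageVolume(mask.voxels.astype(np.float32), mask.affine)
    out = resample_to_grid(vol, target_affine, target_shape, order=0, cval=0.0)
    return BrainMask((out.voxels > 0.5).astype(np.uint8), out.affine)


def resample_to_iso_cube(vol: ImageVolume, side: int = 128, order: int = 1) -> ImageVolume:
    """Resample to a side^3 isotropic cube covering the input field of view.

    One global scale is used on all three axes (no anisotropic stretch), so
    anatomical proportions are preserved; the cube is centered on the input
    volume's center and inherits the input's axis directions.
    """
    if side < 2:
        raise ValueError("side must be >= 2")
    spacing = vol.spacing
    extents = np.array(vol.shape) * spacing
    scale = float(extents.max()) / side
    directions = vol.affine[:3, :3] / spacing  # unit columns
    new_affine = np.eye(4)
    new_affine[:3, :3] = directions * scale
    center = vol.affine[:3, :3] @ ((np.array(vol.shape) - 1) / 2.0) + vol.affine[:3, 3]
    new_affine[:3, 3] = center - new_affine[:3, :3] @ np.full(3, (side - 1) / 2.0)
    return resample_to_grid(vol, new_affine, (side, side, side), order=order)


def world_centroid(vol: ImageVolume, threshold: float) -> np.ndarray:
    """Intensity-weighted centroid (world mm) of voxels above threshold."""
    fg = vol.voxels > threshold
    if not fg.any():
        raise DegenerateInputError("empty foreground: no voxel above threshold")
    idx = np.argwhere(fg).astype(float)
    w = vol.voxels[fg].astype(float)
    centroid_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
    return vol.affine[:3, :3] @ centroid_idx + vol.affine[:3, 3]


def foreground_mask(voxels: np.ndarray, min_background_fraction: float = 0.01) -> np.ndarray:
    """Boolean foreground: everything except the constant background value.

    The background of a cropped/harmonized head volume is an exactly
    constant value (0 on raw volumes; an affine image of 0 after linear
    intensity maps).  It is detected as the modal voxel value when that
    value occupies more than ``min_background_fraction`` of the grid;
    otherwise the whole grid is foreground.  Detecting the mode instead of
    hard-coding zero keeps foreground-based statistics (z-score, GMM fits,
    QC overlap) stable under affine intensity maps.
    """
    vals, counts = np.unique(voxels, return_counts=True)
    top = counts.argmax()
    if counts[top] > min_background_fraction * voxels.size and vals.size > 1:
        return voxels != vals[top]
    return np.ones(voxels.shape, dtype=bool)


# ---------------------------------------------------------------------------
# NIfTI I/O

def load_nifti(path, modality_tag: str = "T1ce") -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(np.asarray(img.get_fdata(), dtype=np.float32), img.affine, modality_tag)


def save_nifti(vol: ImageVolume | BrainMask, path) -> None:
    data = vol.voxels
    img = nib.Nifti1Image(data, vol.affine)
    img.set_qform(vol.affine, code=1)
    img.set_sform(vol.affine, code=1)
    nib.save(img, str(path))


def load_mask(path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return BrainMask((data > 0.5).astype(np.uint8), img.affine)
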