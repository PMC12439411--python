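"""Canonical isotropic-volume reconstruction from 1-3 acquisition planes.

The reference plane (TRA when available) is cropped of black space and
resampled to a ``side``^3 LAS isotropic cube; the remaining planes are
resampled onto that exact grid.  Planes whose foreground center is offset
more than 10 mm from the reference, or whose foreground overlap is below
30%, are flagged as misaligned: they are excluded from fusion and marked
for separate reprocessing.  The surviving planes are min-max rescaled over
their foreground and fused by the voxelwise maximum, which keeps the
highest signal from each acquisition plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dicom_ingest import PLANE_ORDER, PlaneStack, stack_to_volume
from .errors import DegenerateInputError, VetbrainError
from .geometry import (
    ImageVolume,
    crop_foreground,
    foreground_mask,
    reorient_to_las,
    resample_to_grid,
    resample_to_iso_cube,
    world_centroid,
)

__all__ = [
    "AlignmentReport",
    "CanonicalStudy",
    "select_reference",
    "alignment_report",
    "fuse_max",
    "reconstruct",
]

#: foreground for alignment QC: voxels above this percentile of nonzero intensities
QC_PERCENTILE = 60.0


@dataclass
class AlignmentReport:
    """Per-plane alignment quality relative to the reference plane."""

    plane: str
    center_offset_mm: float
    overlap_fraction: float
    flagged: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "plane": self.plane,
            "center_offset_mm": self.center_offset_mm,
            "overlap_fraction": self.overlap_fraction,
            "flagged": self.flagged,
            "note": self.note,
        }


@dataclass
class CanonicalStudy:
    """A fused canonical volume plus the provenance needed to undo it.

    ``per_plane_originals`` maps plane label -> (affine, shape) of the
    volume as ingested, enabling realignment of predicted masks to the
    original slices, size, position and orientation.
    """

    fused: ImageVolume
    per_plane_originals: dict[str, tuple[np.ndarray, tuple[int, int, int]]]
    reports: list[AlignmentReport] = field(default_factory=list)
    reference_plane: str = "TRA"
    flagged_planes: dict[str, ImageVolume] = field(default_factory=dict)
    #: per fused plane: the (min, max) foreground intensities mapped to [0, 1]
    rescale_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = self.fused.shape
        if not (s[0] == s[1] == s[2]):
            raise ValueError("canonical volume must be cubic")


def select_reference(planes: dict[str, ImageVolume] | list[str]) -> str:
    """TRA when present, else first of DOR, SAG."""
    labels = set(planes)
    for label in PLANE_ORDER:
        if label in labels:
            return label
    raise VetbrainError(f"no usable plane among {sorted(labels)}")


def _qc_foreground(vol: ImageVolume) -> tuple[np.ndarray, float]:
    nz = vol.voxels[vol.voxels > 0]
    if nz.size == 0:
        raise DegenerateInputError("volume has no positive voxels for QC foreground")
    thr = float(np.percentile(nz, QC_PERCENTILE))
    return vol.voxels > thr, thr


def alignment_report(
    candidate: ImageVolume,
    reference: ImageVolume,
    offset_threshold_mm: float = 10.0,
    overlap_threshold: float = 0.30,
) -> AlignmentReport:
    """Compare a plane to the reference on the common canonical grid.

    ``center_offset_mm`` is the distance between intensity-weighted
    foreground centroids in world mm; ``overlap_fraction`` is the
    intersection of the two foregrounds divided by the smaller one.  A
    plane is flagged when the offset *exceeds* the threshold (strictly) or
    the overlap falls strictly below the overlap threshold.
    """
    fg_c, thr_c = _qc_foreground(candidate)
    fg_r, thr_r = _qc_foreground(reference)
    if not fg_c.any() or not fg_r.any():
        raise DegenerateInputError("empty QC foreground")
    c1 = world_centroid(candidate, thr_c)
    c2 = world_centroid(reference, thr_r)
    offset = float(np.linalg.norm(c1 - c2))
    if fg_c.shape == fg_r.shape:
        inter = int(np.logical_and(fg_c, fg_r).sum())
    else:
        raise VetbrainError("alignment QC requires both volumes on the common canonical grid")
    overlap = inter / min(int(fg_c.sum()), int(fg_r.sum()))
    flagged = (offset > offset_threshold_mm) or (overlap < overlap_threshold)
    plane = getattr(candidate, "modality_tag", "")
    return AlignmentReport(plane, offset, float(overlap), bool(flagged))


def fuse_max(volumes: list[ImageVolume]) -> ImageVolume:
    """Voxelwise maximum across volumes sharing one grid (shape and affine)."""
    if not volumes:
        raise VetbrainError("fuse_max requires at least one volume")
    first = volumes[0]
    for v in volumes[1:]:
        if v.shape != first.shape or not np.allclose(v.affine, first.affine, atol=1e-6):
            raise VetbrainError("fuse_max inputs must share shape and affine")
    fused = first.voxels
    for v in volumes[1:]:
        fused = np.maximum(fused, v.voxels)
    return ImageVolume(fused, first.affine.copy(), first.modality_tag)


def _rescale_foreground(vol: ImageVolume) -> tuple[ImageVolume, tuple[float, float]]:
    """Min-max rescale intensities to [0, 1] over the volume's foreground."""
    fg = foreground_mask(vol.voxels)
    lo = float(vol.voxels[fg].min())
    hi = float(vol.voxels[fg].max())
    if hi <= lo:
        raise DegenerateInputError("constant foreground cannot be rescaled")
    out = np.clip((vol.voxels - lo) / (hi - lo), 0.0, 1.0)
    out[~fg] = 0.0
    return ImageVolume(out.astype(np.float32), vol.affine, vol.modality_tag), (lo, hi)


def reconstruct(
    study: list[PlaneStack],
    side: int = 128,
    offset_threshold_mm: float = 10.0,
    overlap_threshold: float = 0.30,
) -> CanonicalStudy:
    """Build the fused side^3 LAS isotropic canonical volume from 1-3 planes.

    Flagged planes are excluded from fusion; each is kept as its own
    single-plane canonical reconstruction (``flagged_planes``) so it can be
    reprocessed separately downstream.
    """
    if not 1 <= len(study) <= 3:
        raise VetbrainError("reconstruct expects 1-3 plane stacks")
    volumes: dict[str, ImageVolume] = {}
    originals: dict[str, tuple[np.ndarray, tuple[int, int, int]]] = {}
    for stack in study:
        vol = stack_to_volume(stack)
        originals[stack.plane] = (vol.affine.copy(), vol.shape)
        volumes[stack.plane] = reorient_to_las(vol)

    ref_label = select_reference(volumes)
    ref = volumes[ref_label]
    ref_cropped, _ = crop_foreground(ref, threshold=float(ref.voxels.min()))
    canonical_ref = resample_to_iso_cube(ref_cropped, side=side, order=1)

    reports: list[AlignmentReport] = []
    flagged: dict[str, ImageVolume] = {}
    rescales: dict[str, tuple[float, float]] = {}
    ref_rescaled, rescales[ref_label] = _rescale_foreground(canonical_ref)
    to_fuse = [ref_rescaled]
    for label, vol in volumes.items():
        if label == ref_label:
            continue
        on_grid = resample_to_grid(vol, canonical_ref.affine, canonical_ref.shape, order=1)
        rep = alignment_report(on_grid, canonical_ref, offset_threshold_mm, overlap_threshold)
        rep.plane = label
        if rep.flagged:
            rep.note = "reprocess separately"
            cropped, _ = crop_foreground(vol, threshold=float(vol.voxels.min()))
            flagged[label] = resample_to_iso_cube(cropped, side=side, order=1)
        else:
            rescaled, rescales[label] = _rescale_foreground(on_grid)
            to_fuse.append(rescaled)
        reports.append(rep)

    fused = fuse_max(to_fuse)
    fused.modality_tag = canonical_ref.modality_tag
    return CanonicalStudy(
        fused=fused,
        per_plane_originals=originals,
        reports=reports,
        reference_plane=ref_label,
        flagged_planes=flagged,
        rescale_params=rescales,
    )
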