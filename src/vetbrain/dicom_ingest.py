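"""Read DICOM slice files into per-plane stacks and geometric volumes.

Veterinary MRI studies are stored as individual 2D slices per acquisition
plane — transversal (TRA), dorsal (DOR) and sagittal (SAG).  This module
groups slice files by series, orders them along the slice normal, labels
the plane from the normal's dominant patient axis, and assembles an
:class:`~vetbrain.geometry.ImageVolume` whose affine reproduces the DICOM
Image Position/Orientation mapping exactly (no resampling at ingest).

DICOM patient coordinates are LPS; they are converted to the package's
RAS+ world frame on ingest (x and y components negated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom

from .errors import InconsistencyError, VetbrainError
from .geometry import ImageVolume

__all__ = ["PlaneStack", "load_study", "stack_to_volume", "classify_plane"]

log = logging.getLogger(__name__)

_LPS_TO_RAS = np.array([-1.0, -1.0, 1.0])

#: plane priority used for tie-breaks (and for reference selection downstream)
PLANE_ORDER = ("TRA", "DOR", "SAG")


@dataclass
class PlaneStack:
    """Ordered 2D slices of one acquisition plane with DICOM-derived geometry.

    ``slices`` is an (n_slices, rows, cols) array; ``positions`` holds the
    per-slice origin (world RAS mm of pixel (0, 0)); ``orientation_cosines``
    is the six-tuple (row-direction, column-direction) in RAS; spacings are
    in mm.
    """

    slices: np.ndarray
    plane: str
    orientation_cosines: np.ndarray
    positions: np.ndarray
    pixel_spacing: np.ndarray
    slice_spacing: float
    series_id: str = ""
    modality_tag: str = "T1ce"

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float32)
        if self.slices.ndim != 3:
            raise ValueError("slices must be (n_slices, rows, cols)")
        self.orientation_cosines = np.asarray(self.orientation_cosines, dtype=float).reshape(6)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.pixel_spacing = np.asarray(self.pixel_spacing, dtype=float).reshape(2)
        if len(self.positions) != len(self.slices):
            raise ValueError("one position per slice required")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be > 0")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def normal(self) -> np.ndarray:
        row = self.orientation_cosines[:3]
        col = self.orientation_cosines[3:]
        return np.cross(row, col)


def classify_plane(normal: np.ndarray) -> str:
    """Label a slice normal: superior -> TRA, anterior -> DOR, left/right -> SAG.

    The label comes from the arg-max absolute component, so it is invariant
    to the normal's sign; exact ties break in the order TRA > DOR > SAG.
    """
    a = np.abs(np.asarray(normal, dtype=float))
    # strict '>' walks axes in priority order: z (TRA), then y (DOR), then x (SAG)
    best_axis, best = 2, a[2]
    for axis in (1, 0):
        if a[axis] > best:
            best_axis, best = axis, a[axis]
    return {2: "TRA", 1: "DOR", 0: "SAG"}[best_axis]


def _read_slices(directory: Path) -> list[pydicom.Dataset]:
    datasets = []
    for path in sorted(directory.rglob("*")):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(path), force=True)
        except Exception:
            continue
        if "PixelData" not in ds or "ImagePositionPatient" not in ds:
            continue
        datasets.append(ds)
    return datasets


def _slice_pixels(ds: pydicom.Dataset) -> np.ndarray:
    arr = ds.pixel_array.astype(np.float32)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def load_study(directory) -> list[PlaneStack]:
    """Group the DICOM files of a study directory into per-plane stacks.

    Files are grouped by SeriesInstanceUID, sorted by the projection of
    their position onto the slice normal, and labelled by plane.  When
    several series map to the same plane the one with the most slices is
    kept and the others are logged.
    """
    directory = Path(directory)
    datasets = _read_slices(directory)
    if not datasets:
        raise VetbrainError(f"no readable DICOM files with pixel data in {directory}")

    series: dict[str, list[pydicom.Dataset]] = {}
    for ds in datasets:
        series.setdefault(str(getattr(ds, "SeriesInstanceUID", "unknown")), []).append(ds)

    stacks: list[PlaneStack] = []
    for uid, group in series.items():
        ref = group[0]
        cos_lps = np.asarray([float(v) for v in ref.ImageOrientationPatient])
        spacing = np.asarray([float(v) for v in ref.PixelSpacing])
        shape = (int(ref.Rows), int(ref.Columns))
        for ds in group[1:]:
            if (int(ds.Rows), int(ds.Columns)) != shape:
                raise InconsistencyError(f"mixed slice shapes within series {uid}")
            if not np.allclose([float(v) for v in ds.ImageOrientationPatient], cos_lps, atol=1e-4):
                raise InconsistencyError(f"mixed orientations within series {uid}")
            if not np.allclose([float(v) for v in ds.PixelSpacing], spacing, rtol=1e-3):
                raise InconsistencyError(f"mixed pixel spacings within series {uid}")

        row = cos_lps[:3] * _LPS_TO_RAS
        col = cos_lps[3:] * _LPS_TO_RAS
        normal = np.cross(row, col)
        positions = np.array(
            [[float(v) for v in ds.ImagePositionPatient] for ds in group]
        ) * _LPS_TO_RAS
        proj = positions @ normal
        order = np.argsort(proj)
        positions = positions[order]
        proj = proj[order]
        if len(group) > 1:
            gaps = np.diff(proj)
            if np.any(gaps <= 0):
                raise InconsistencyError(f"duplicate or non-monotone slice positions in series {uid}")
            slice_spacing = float(np.median(gaps))
        else:
            slice_spacing = float(getattr(ref, "SliceThickness", 1.0))
        pixels = np.stack([_slice_pixels(group[i]) for i in order])
        device = getattr(ref, "DeviceSerialNumber", None)
        if device is not None:
            log.info("series %s acquired on device %s", uid, device)
        stacks.append(
            PlaneStack(
                slices=pixels,
                plane=classify_plane(normal),
                orientation_cosines=np.concatenate([row, col]),
                positions=positions,
                pixel_spacing=spacing,
                slice_spacing=slice_spacing,
                series_id=uid,
                modality_tag=str(getattr(ref, "SeriesDescription", "T1ce")) or "T1ce",
            )
        )

    # keep the largest series per plane; log the duplicates
    by_plane: dict[str, PlaneStack] = {}
    for stack in stacks:
        kept = by_plane.get(stack.plane)
        if kept is None or stack.n_slices > kept.n_slices:
            if kept is not None:
                log.warning("dropping duplicate %s series %s (%d slices)", stack.plane, kept.series_id, kept.n_slices)
            by_plane[stack.plane] = stack
        else:
            log.warning("dropping duplicate %s series %s (%d slices)", stack.plane, stack.series_id, stack.n_slices)
    return [by_plane[p] for p in PLANE_ORDER if p in by_plane]


def stack_to_volume(stack: PlaneStack) -> ImageVolume:
    """Assemble a geometric volume from an ordered slice stack.

    Voxel (r, c, s) maps to ``position[s] + col_dir * dr * r + row_dir * dc * c``,
    the DICOM patient-space mapping expressed in RAS.  At least two slices
    are needed to fix the inter-slice vector; slice gaps must be uniform to
    1% or the series is rejected.
    """
    if stack.n_slices < 2:
        raise VetbrainError("a volume requires >= 2 slices to fix the slice spacing")
    row = stack.orientation_cosines[:3]
    col = stack.orientation_cosines[3:]
    steps = np.diff(stack.positions, axis=0)
    lens = np.linalg.norm(steps, axis=1)
    mean_len = float(lens.mean())
    if np.any(np.abs(lens - mean_len) > 0.01 * mean_len):
        raise InconsistencyError("non-uniform slice gaps exceed 1% tolerance")
    slice_vec = steps.mean(axis=0)

    n, rows, cols = stack.slices.shape
    voxels = np.moveaxis(stack.slices, 0, 2)  # (rows, cols, slices)
    affine = np.eye(4)
    affine[:3, 0] = col * stack.pixel_spacing[0]  # increasing row index
    affine[:3, 1] = row * stack.pixel_spacing[1]  # increasing column index
    affine[:3, 2] = slice_vec
    affine[:3, 3] = stack.positions[0]
    return ImageVolume(voxels, affine, stack.modality_tag)
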