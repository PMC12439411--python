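"""Synthetic multi-plane canine-head studies with exact ground-truth masks.

The phantom is built from nested ellipsoids on a high-resolution isotropic
grid: head soft tissue (bright, subcutaneous-fat-like), a dark skull
shell, and a brain ellipsoid carrying two to three Gaussian tissue
classes, optionally with a spherical lesion, a smooth multiplicative bias
field, and additive Gaussian noise inside the head.  The ground-truth
brain mask is the brain ellipsoid itself, so truth volumes have closed
forms and every downstream stage can be checked analytically.

The skull is darker than the brain and the subcutaneous layer brighter,
so naive global thresholding fails while a *band* of intensities isolates
the brain — the property the intensity-band oracle backend exploits.

Each reference phantom can be virtually "scanned" into anisotropic 2D
slice stacks per acquisition plane (TRA/DOR/SAG) with realistic slice
thicknesses (1.5-5 mm) and in-plane spacings (0.18-0.86 mm), optional
world-space offsets simulating repositioning between acquisitions, and
optional emission as DICOM series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

from .dicom_ingest import PlaneStack
from .errors import VetbrainError
from .geometry import BrainMask, ImageVolume

__all__ = ["PlaneSpec", "PhantomSpec", "make_reference", "sample_plane", "make_study", "emit_dicom"]

#: unit row/column direction cosines (RAS) per acquisition plane
_PLANE_COSINES = {
    "TRA": (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),   # normal +S
    "DOR": (np.array([1.0, 0, 0]), np.array([0, 0, -1.0])),  # normal +A
    "SAG": (np.array([0, 1.0, 0]), np.array([0, 0, -1.0])),  # normal -R (left)
}


@dataclass
class PlaneSpec:
    """Acquisition geometry of one plane: thickness, in-plane spacing, offset."""

    thickness_mm: float = 3.0
    inplane_mm: float = 0.5
    offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 1.5 <= self.thickness_mm <= 5.0:
            raise ValueError("slice thickness must lie in [1.5, 5] mm")
        if not 0.18 <= self.inplane_mm <= 0.86:
            raise ValueError("in-plane spacing must lie in [0.18, 0.86] mm")


@dataclass
class PhantomSpec:
    """Generating parameters of one synthetic head study.

    Half-axes are in mm; intensities are on an arbitrary [0, 1]-ish scale
    with background fixed at 0.  Defaults model a mesaticephalic mid-size
    dog; dolicho-/brachycephalic variants are produced by stretching or
    compressing the anterior axis.
    """

    seed: int = 0
    head_axes_mm: tuple[float, float, float] = (38.0, 55.0, 40.0)
    brain_axes_mm: tuple[float, float, float] = (24.0, 32.0, 22.0)
    skull_thickness_mm: float = 2.5
    tissue_classes: tuple[tuple[float, float], ...] = ((0.45, 0.02), (0.55, 0.02), (0.62, 0.02))
    skull_intensity: tuple[float, float] = (0.12, 0.02)
    head_intensity: tuple[float, float] = (0.88, 0.03)
    lesion: tuple[tuple[float, float, float], float, float, float] | None = None
    bias_field: tuple[float, float] | None = None  # (amplitude, length scale mm)
    noise_sd: float = 0.0
    plane_specs: dict[str, PlaneSpec] = field(
        default_factory=lambda: {
            "TRA": PlaneSpec(3.0, 0.5),
            "DOR": PlaneSpec(4.0, 0.6),
            "SAG": PlaneSpec(3.5, 0.55),
        }
    )
    resolution_mm: float = 0.5
    margin_mm: float = 6.0

    def __post_init__(self) -> None:
        brain = np.asarray(self.brain_axes_mm, float)
        head = np.asarray(self.head_axes_mm, float)
        if np.any(brain + self.skull_thickness_mm >= head):
            raise VetbrainError("brain + skull shell must fit strictly inside the head")
        if self.resolution_mm > 0.5:
            raise ValueError("reference resolution must be <= 0.5 mm isotropic")


def _ellipsoid(coords: list[np.ndarray], axes: np.ndarray) -> np.ndarray:
    r2 = sum((c / a) ** 2 for c, a in zip(coords, axes))
    return r2 <= 1.0


def make_reference(spec: PhantomSpec) -> tuple[ImageVolume, BrainMask]:
    """Render the high-resolution phantom volume and its exact truth mask.

    Deterministic given ``spec.seed``; intensities are float32 with
    background exactly 0.
    """
    rng = np.random.default_rng(spec.seed)
    head = np.asarray(spec.head_axes_mm, float)
    res = spec.resolution_mm
    half_extent = head + spec.margin_mm
    shape = tuple(int(np.ceil(2 * h / res)) for h in half_extent)
    affine = np.diag([res, res, res, 1.0])
    affine[:3, 3] = -(np.array(shape) - 1) / 2.0 * res  # head centered on world 0

    coords = [
        (np.arange(n) * res + affine[i, 3]).astype(np.float64) for i, n in enumerate(shape)
    ]
    grids = np.meshgrid(*coords, indexing="ij", sparse=True)

    brain = _ellipsoid(grids, np.asarray(spec.brain_axes_mm, float))
    skull_outer = _ellipsoid(grids, np.asarray(spec.brain_axes_mm, float) + spec.skull_thickness_mm)
    head_mask = _ellipsoid(grids, head)
    skull = skull_outer & ~brain
    soft = head_mask & ~skull_outer

    vox = np.zeros(shape, dtype=np.float64)
    mu, sd = spec.head_intensity
    vox[soft] = rng.normal(mu, sd, int(soft.sum()))
    mu, sd = spec.skull_intensity
    vox[skull] = rng.normal(mu, sd, int(skull.sum()))

    # brain tissue classes in concentric shells (WM core, GM, peripheral CSF-ish)
    r2 = sum((g / a) ** 2 for g, a in zip(grids, np.asarray(spec.brain_axes_mm, float)))
    n_classes = len(spec.tissue_classes)
    edges = np.linspace(0.0, 1.0, n_classes + 1) ** 0.5  # equalish volume shells
    for c, (mu, sd) in enumerate(spec.tissue_classes):
        shell = brain & (r2 >= edges[c] ** 2) & (r2 <= edges[c + 1] ** 2)
        vox[shell] = rng.normal(mu, sd, int(shell.sum()))

    if spec.lesion is not None:
        center, radius, mu, sd = spec.lesion
        lesion = sum((g - c) ** 2 for g, c in zip(grids, np.asarray(center, float))) <= radius**2
        lesion_in = lesion & head_mask
        vox[lesion_in] = rng.normal(mu, sd, int(lesion_in.sum()))

    if spec.noise_sd > 0:
        vox[head_mask] += rng.normal(0.0, spec.noise_sd, int(head_mask.sum()))

    if spec.bias_field is not None:
        amp, length = spec.bias_field
        sigma = max(length / res, 1.0)
        low = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        peak = np.abs(low).max()
        if peak > 0:
            vox *= 1.0 + amp * low / peak

    np.clip(vox, 0.001, None, out=vox, where=head_mask)
    vox[~head_mask] = 0.0
    return (
        ImageVolume(vox.astype(np.float32), affine, "T1ce"),
        BrainMask(brain.astype(np.uint8), affine.copy()),
    )


def ellipsoid_mask_on_grid(
    axes_mm, affine: np.ndarray, shape: tuple[int, int, int], center_mm=(0.0, 0.0, 0.0)
) -> BrainMask:
    """Evaluate an analytic origin-centered ellipsoid at the voxel centers of any grid."""
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    aff = np.asarray(affine, float)
    world = aff[:3, :3] @ idx + aff[:3, 3:4] - np.asarray(center_mm, float)[:, None]
    axes = np.asarray(axes_mm, float)
    inside = ((world / axes[:, None]) ** 2).sum(axis=0) <= 1.0
    return BrainMask(inside.reshape(shape).astype(np.uint8), aff)


def truth_mask_on_grid(
    spec: PhantomSpec, affine: np.ndarray, shape: tuple[int, int, int]
) -> BrainMask:
    """The exact brain truth mask resampled analytically onto any grid."""
    return ellipsoid_mask_on_grid(spec.brain_axes_mm, affine, shape)


def sample_plane(
    ref: ImageVolume,
    plane: str,
    thickness_mm: float,
    inplane_mm: float,
    offset_mm=(0.0, 0.0, 0.0),
    modality_tag: str = "T1ce",
) -> PlaneStack:
    """Virtually scan the reference into an anisotropic 2D slice stack.

    The stack's recorded geometry covers the reference field of view; the
    world offset shifts where the anatomy *appears* relative to the
    recorded coordinates, simulating patient repositioning between
    acquisitions.
    """
    if plane not in _PLANE_COSINES:
        raise VetbrainError(f"unknown plane {plane!r}")
    row, col = _PLANE_COSINES[plane]
    normal = np.cross(row, col)
    offset = np.asarray(offset_mm, float)

    corners_idx = np.array(np.meshgrid(*[[0, n - 1] for n in ref.shape], indexing="ij"))
    corners = ref.world_coords(corners_idx.reshape(3, -1).T)
    extent_row = corners @ row
    extent_col = corners @ col
    extent_nrm = corners @ normal
    if thickness_mm > (extent_nrm.max() - extent_nrm.min()):
        raise VetbrainError("slice thickness exceeds the head extent along the normal")

    n_rows = int(np.floor((extent_col.max() - extent_col.min()) / inplane_mm)) + 1
    n_cols = int(np.floor((extent_row.max() - extent_row.min()) / inplane_mm)) + 1
    n_slices = int(np.floor((extent_nrm.max() - extent_nrm.min()) / thickness_mm)) + 1
    origin = row * extent_row.min() + col * extent_col.min() + normal * extent_nrm.min()

    affine = np.eye(4)
    affine[:3, 0] = col * inplane_mm     # increasing row index
    affine[:3, 1] = row * inplane_mm     # increasing column index
    affine[:3, 2] = normal * thickness_mm
    affine[:3, 3] = origin

    # sample the anatomy displaced by +offset: content at recorded point p
    # comes from the reference at p - offset
    m = np.linalg.inv(ref.affine) @ affine
    idx = np.indices((n_rows, n_cols, n_slices), dtype=np.float32).reshape(3, -1)
    src = m[:3, :3].astype(np.float32) @ idx + m[:3, 3:4].astype(np.float32)
    shift = np.linalg.inv(ref.affine[:3, :3]) @ offset
    src -= shift[:, None].astype(np.float32)
    vox = ndimage.map_coordinates(
        ref.voxels.astype(np.float32, copy=False), src, order=1, mode="constant", cval=0.0
    ).reshape(n_rows, n_cols, n_slices)

    positions = origin[None, :] + normal[None, :] * thickness_mm * np.arange(n_slices)[:, None]
    return PlaneStack(
        slices=np.moveaxis(vox, 2, 0),
        plane=plane,
        orientation_cosines=np.concatenate([row, col]),
        positions=positions,
        pixel_spacing=np.array([inplane_mm, inplane_mm]),
        slice_spacing=thickness_mm,
        series_id=f"phantom-{plane}",
        modality_tag=modality_tag,
    )


def make_study(spec: PhantomSpec) -> tuple[list[PlaneStack], BrainMask, dict]:
    """Generate the full multi-plane study: stacks, truth mask, metadata.

    Metadata records every generating parameter plus measured tissue-class
    voxel fractions of the head foreground, from which quantile-band
    thresholds for the oracle backend can be derived.
    """
    ref, truth = make_reference(spec)
    stacks = [
        sample_plane(ref, plane, ps.thickness_mm, ps.inplane_mm, ps.offset_mm)
        for plane, ps in spec.plane_specs.items()
    ]
    fg = ref.voxels > 0
    n_fg = int(fg.sum())
    brain = truth.voxels > 0
    skull_band_hi = (spec.skull_intensity[0] + min(m for m, _ in spec.tissue_classes)) / 2
    frac_below = float(np.sum(fg & (ref.voxels < skull_band_hi)) / n_fg)
    frac_brain = float(np.sum(brain) / n_fg)
    meta = {
        "seed": spec.seed,
        "head_axes_mm": list(spec.head_axes_mm),
        "brain_axes_mm": list(spec.brain_axes_mm),
        "skull_thickness_mm": spec.skull_thickness_mm,
        "tissue_classes": [list(t) for t in spec.tissue_classes],
        "noise_sd": spec.noise_sd,
        "bias_field": list(spec.bias_field) if spec.bias_field else None,
        "lesion": None if spec.lesion is None else {
            "center_mm": list(spec.lesion[0]), "radius_mm": spec.lesion[1],
            "mean": spec.lesion[2], "sd": spec.lesion[3],
        },
        "planes": {
            p: {"thickness_mm": ps.thickness_mm, "inplane_mm": ps.inplane_mm,
                "offset_mm": list(ps.offset_mm)}
            for p, ps in spec.plane_specs.items()
        },
        "resolution_mm": spec.resolution_mm,
        "foreground_fraction_below_brain_band": frac_below,
        "brain_foreground_fraction": frac_brain,
    }
    return stacks, truth, meta


def oracle_band_backend(
    study,
    harmonized: ImageVolume,
    tissue_classes,
    n_sigma: float = 3.0,
    opening_iterations: int = 1,
):
    """Build the intensity-band oracle for a reconstructed phantom study.

    The phantom's brain classes occupy a known raw band
    ``[min(mu) - n_sigma * max(sd), max(mu) + n_sigma * max(sd)]``.  That
    band is mapped into harmonized units through the pipeline's recorded
    intensity transforms: each fused plane's min-max rescale (taking the
    widest image of the band across planes, since fusion is a voxelwise
    max), then the canonical-to-harmonized map, estimated as the affine
    best fitting matched quantiles (harmonization is a z-score, exactly
    affine, preceded by a weak N4 correction).  One opening iteration cuts
    partial-volume bridges across the thin skull.

    This is test instrumentation: it stands in for a trained segmenter on
    phantoms only, and it knows the generating intensity classes.
    """
    from .geometry import foreground_mask as _fg
    from .segmentation import IntensityBandBackend

    mus = [m for m, _ in tissue_classes]
    sds = [s for _, s in tissue_classes]
    raw_lo = min(mus) - n_sigma * max(sds)
    raw_hi = max(mus) + n_sigma * max(sds)
    if not study.rescale_params:
        raise VetbrainError("study carries no rescale provenance")
    band_lo = min((raw_lo - lo) / (hi - lo) for lo, hi in study.rescale_params.values())
    band_hi = max((raw_hi - lo) / (hi - lo) for lo, hi in study.rescale_params.values())

    fg = _fg(study.fused.voxels)
    qs = np.linspace(0.02, 0.98, 49)
    a, b = np.polyfit(
        np.quantile(study.fused.voxels[fg].astype(np.float64), qs),
        np.quantile(harmonized.voxels[fg].astype(np.float64), qs),
        1,
    )
    return IntensityBandBackend(
        a * band_lo + b, a * band_hi + b, opening_iterations=opening_iterations
    )


def oracle_extract(stacks, tissue_classes, cfg=None):
    """Run the full pipeline on a phantom study with the intensity oracle.

    Mirrors the production pipeline (reconstruct -> harmonize -> segment ->
    post-process -> map back to each original plane) but constructs the
    band backend from the phantom's known tissue classes after
    harmonization.  Returns (canonical mask, per-plane masks, study).
    """
    from .config import PipelineConfig
    from .harmonization import BiasCorrectionParams, bias_correct, zscore
    from .mask_remap import map_to_original
    from .reconstruction import CanonicalStudy, _rescale_foreground, reconstruct
    from .segmentation import postprocess, segment

    cfg = cfg or PipelineConfig()
    study = reconstruct(
        stacks, side=cfg.side,
        offset_threshold_mm=cfg.offset_threshold_mm,
        overlap_threshold=cfg.overlap_threshold,
    )
    params = BiasCorrectionParams(
        shrink_factor=cfg.shrink_factor, mask_percentile=cfg.mask_percentile
    )

    def _segment_one(vol, st):
        harmonized = zscore(bias_correct(vol, params))
        backend = oracle_band_backend(st, harmonized, tissue_classes)
        return postprocess(segment(harmonized, backend), cfg.center_radius_mm)

    canonical_mask = _segment_one(study.fused, study)
    per_plane = {}
    for plane, (affine, shape) in study.per_plane_originals.items():
        if plane in study.flagged_planes:
            # flagged planes are reprocessed separately on their own grid
            solo, lohi = _rescale_foreground(study.flagged_planes[plane])
            solo_study = CanonicalStudy(
                fused=solo,
                per_plane_originals={plane: (affine, shape)},
                reference_plane=plane,
                rescale_params={plane: lohi},
            )
            mask = _segment_one(solo, solo_study)
        else:
            mask = canonical_mask
        per_plane[plane] = map_to_original(mask, affine, shape)
    return canonical_mask, per_plane, study


_RAS_TO_LPS = np.array([-1.0, -1.0, 1.0])


def emit_dicom(stack: PlaneStack, directory, study_uid: str | None = None) -> list[Path]:
    """Write a stack as one uncompressed DICOM file per slice.

    Geometry tags (ImageOrientationPatient, ImagePositionPatient,
    PixelSpacing) are converted back to DICOM's LPS frame; intensities are
    scaled to uint16 with a RescaleSlope restoring the float values.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_uid = study_uid or generate_uid()
    series_uid = generate_uid()
    peak = float(stack.slices.max())
    slope = peak / 60000.0 if peak > 0 else 1.0
    row = stack.orientation_cosines[:3] * _RAS_TO_LPS
    col = stack.orientation_cosines[3:] * _RAS_TO_LPS

    paths = []
    for s in range(stack.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = stack.modality_tag
        ds.Modality = "MR"
        ds.DeviceSerialNumber = "vetbrain-phantom"
        ds.InstanceNumber = s + 1
        ds.ImageOrientationPatient = [float(v) for v in np.concatenate([row, col])]
        ds.ImagePositionPatient = [float(v) for v in stack.positions[s] * _RAS_TO_LPS]
        ds.PixelSpacing = [float(stack.pixel_spacing[0]), float(stack.pixel_spacing[1])]
        ds.SliceThickness = float(stack.slice_spacing)
        ds.Rows, ds.Columns = stack.slices.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.round(stack.slices[s] / slope).astype(np.uint16).tobytes()
        path = directory / f"{stack.plane}_{s:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths
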