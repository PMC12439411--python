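"""Pluggable brain-segmentation backends and mask post-processing.

A backend maps a canonical harmonized volume to a probability (or binary)
mask on the same grid.  Two backends ship with the package: an
external-command adapter that round-trips NIfTI files through any
command-line segmenter (e.g. an nnU-Net inference call), and an
intensity-band oracle used by the test suite on phantoms whose brain
class occupies a known intensity band.

Post-processing keeps only the largest 26-connected component of the
predicted mask and removes voxels far from that component's centroid,
discarding artefacts far from the brain center.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .errors import BackendError, EmptyMaskError, TieBreakWarning
from .geometry import (
    BrainMask,
    ImageVolume,
    foreground_mask,
    load_mask,
    save_nifti,
)

__all__ = [
    "SegmentationBackend",
    "IntensityBandBackend",
    "ExternalCommandBackend",
    "segment",
    "postprocess",
]


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract: canonical volume in, probabilities in [0, 1] on the same grid out."""

    name: str

    def predict(self, vol: ImageVolume) -> np.ndarray: ...


@dataclass
class IntensityBandBackend:
    """Oracle backend: brain = voxels inside a known intensity band.

    With ``quantiles=True`` the band bounds are quantile levels of the
    foreground intensity distribution rather than absolute intensities;
    quantile bands are invariant under any monotone intensity map, so they
    survive z-scoring and min-max rescaling unchanged.

    ``opening_iterations`` applies that many iterations of binary opening
    (6-connected) to the band mask, severing thin partial-volume bridges a
    pure threshold cannot avoid on anisotropic acquisitions; 0 keeps the
    raw band, which is exact on noise-free separable phantoms.
    """

    low: float
    high: float
    quantiles: bool = False
    opening_iterations: int = 0
    name: str = "intensity-band"

    def predict(self, vol: ImageVolume) -> np.ndarray:
        lo, hi = self.low, self.high
        if self.quantiles:
            fg = vol.voxels[foreground_mask(vol.voxels)]
            lo, hi = np.quantile(fg, [self.low, self.high])
        inside = (vol.voxels >= lo) & (vol.voxels <= hi) & foreground_mask(vol.voxels)
        if self.opening_iterations > 0 and inside.any():
            inside = ndimage.binary_opening(
                inside,
                structure=ndimage.generate_binary_structure(3, 1),
                iterations=self.opening_iterations,
            )
        return inside.astype(np.float32)


@dataclass
class ExternalCommandBackend:
    """Adapter running a shell command with {input} and {output} NIfTI slots."""

    command_template: str
    timeout: float = 600.0
    env: dict | None = None
    name: str = "external-command"

    def predict(self, vol: ImageVolume) -> np.ndarray:
        with tempfile.TemporaryDirectory(prefix="vetbrain-backend-") as tmp:
            in_path = Path(tmp) / "input.nii.gz"
            out_path = Path(tmp) / "output.nii.gz"
            save_nifti(vol, in_path)
            cmd = self.command_template.format(input=in_path, output=out_path)
            try:
                proc = subprocess.run(
                    cmd, shell=True, capture_output=True, text=True,
                    timeout=self.timeout, env=self.env,
                )
            except subprocess.TimeoutExpired as exc:
                raise BackendError(f"backend timed out after {self.timeout}s: {cmd}") from exc
            if proc.returncode != 0:
                raise BackendError(
                    f"backend exited {proc.returncode}: {cmd}\nstderr: {proc.stderr[-2000:]}"
                )
            if not out_path.exists():
                raise BackendError(f"backend produced no output file: {cmd}")
            return load_mask(out_path).voxels.astype(np.float32)


def segment(vol: ImageVolume, backend: SegmentationBackend) -> BrainMask:
    """Run a backend and threshold its probabilities at 0.5."""
    try:
        probs = np.asarray(backend.predict(vol))
    except BackendError:
        raise
    except Exception as exc:  # backend contract violation surfaces with context
        raise BackendError(f"backend {backend.name!r} failed: {exc}") from exc
    if probs.shape != vol.shape:
        raise BackendError(
            f"backend {backend.name!r} returned shape {probs.shape}, expected {vol.shape}"
        )
    if probs.min() < 0 or probs.max() > 1:
        raise BackendError(f"backend {backend.name!r} probabilities outside [0, 1]")
    return BrainMask((probs >= 0.5).astype(np.uint8), vol.affine.copy())


_CONN26 = np.ones((3, 3, 3), dtype=int)


def postprocess(mask: BrainMask, center_radius_mm: float = 80.0) -> BrainMask:
    """Keep the largest 26-connected component; drop voxels far from its centroid.

    Voxels farther than ``center_radius_mm`` (world mm) from the retained
    component's centroid are removed.  Equal-size component ties keep the
    component containing the lexicographically smallest voxel index and
    warn.  Idempotent, and never adds voxels.
    """
    if mask.count() == 0:
        raise EmptyMaskError("predicted mask is empty")
    labels, n = ndimage.label(mask.voxels, structure=_CONN26)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(counts.argmax())
    ties = np.flatnonzero(counts == counts[best])
    if len(ties) > 1:
        # the component whose first voxel appears earliest in C order wins
        flat = labels.ravel()
        first = {int(lab): int(np.argmax(flat == lab)) for lab in ties}
        best = min(first, key=first.get)
        warnings.warn(
            f"{len(ties)} equal-size components; keeping the lowest-index one",
            TieBreakWarning,
        )
    kept = labels == best

    idx = np.argwhere(kept).astype(float)
    world = idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    centroid = world.mean(axis=0)
    dist = np.linalg.norm(world - centroid, axis=1)
    keep = dist <= center_radius_mm
    out = np.zeros_like(mask.voxels)
    sel = np.argwhere(kept)[keep]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    return BrainMask(out, mask.affine.copy())
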