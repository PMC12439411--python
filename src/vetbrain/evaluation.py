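"""Segmentation metrics, subject-stratified fold splitting, ROI preprocessing.

Scores follow the standard overlap definitions

    Dice = 2 TP / (2 TP + FP + FN)        IoU (Jaccard) = TP / (TP + FP + FN)
    sensitivity = TP / (TP + FN)          specificity = TN / (TN + FP)

with the identity Dice = 2 IoU / (1 + IoU) holding by construction.
Fold splitting is leave-subject-out: every image (original or augmented)
of one subject lands in exactly one fold, so a model can never see a test
subject's anatomy during training.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .errors import DegenerateInputError, EmptyMaskError, VetbrainError
from .geometry import BrainMask, ImageVolume

__all__ = ["SegmentationScores", "score", "split_leave_subject_out", "roi_preprocess"]


@dataclass
class SegmentationScores:
    """Voxel confusion counts plus the four derived overlap metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    dice: float
    iou: float
    sensitivity: float
    specificity: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "dice": self.dice, "iou": self.iou,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "degenerate": self.degenerate,
        }


def _safe_ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 1.0, True  # empty-denominator convention: perfect but flagged
    return num / den, False


def score(pred: BrainMask, truth: BrainMask) -> SegmentationScores:
    """Exhaustive voxel comparison of a predicted and a ground-truth mask."""
    if pred.shape != truth.shape:
        raise VetbrainError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    p = pred.voxels > 0
    t = truth.voxels > 0
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    dice, d1 = _safe_ratio(2 * tp, 2 * tp + fp + fn)
    iou, d2 = _safe_ratio(tp, tp + fp + fn)
    sens, d3 = _safe_ratio(tp, tp + fn)
    spec, d4 = _safe_ratio(tn, tn + fp)
    return SegmentationScores(tp, fp, fn, tn, dice, iou, sens, spec, d1 or d2 or d3 or d4)


def split_leave_subject_out(
    subjects: Sequence[Hashable], k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Partition item indices into k folds that never split a subject.

    ``subjects[i]`` tags item i with its subject id.  Subjects are shuffled
    deterministically, then assigned greedily (largest group first) to the
    currently smallest fold, so fold sizes are as equal as the subject
    grouping permits.  Returns k index arrays.
    """
    if k < 1:
        raise VetbrainError("k must be >= 1")
    groups: dict[Hashable, list[int]] = defaultdict(list)
    for i, s in enumerate(subjects):
        groups[s].append(i)
    if len(groups) < k:
        raise VetbrainError(f"{len(groups)} subjects cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = sorted(groups)
    rng.shuffle(order)
    # largest groups first (stable within equal sizes) for tight balancing
    order.sort(key=lambda s: -len(groups[s]))
    folds: list[list[int]] = [[] for _ in range(k)]
    for s in order:
        smallest = min(range(k), key=lambda f: (len(folds[f]), f))
        folds[smallest].extend(groups[s])
    return [np.array(sorted(f), dtype=int) for f in folds]


def roi_preprocess(
    vol: ImageVolume, mask: BrainMask, margin_vox: int = 0
) -> ImageVolume:
    """Crop to the mask bounding box (+margin) and normalize the histogram.

    The brain bounding box is dilated by ``margin_vox`` voxels per side and
    clipped to the grid; in-box intensities are clipped to their [p1, p99]
    percentile band and rescaled to [0, 1].  This is the preprocessing a
    downstream classifier sees instead of the raw head scan.
    """
    if vol.shape != mask.shape:
        raise VetbrainError("image and mask must share one grid")
    if mask.count() == 0:
        raise EmptyMaskError("cannot build an ROI from an empty mask")
    idx = np.argwhere(mask.voxels > 0)
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin_vox, vol.shape)
    box = vol.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)
    p1, p99 = np.percentile(box, [1, 99])
    if p99 <= p1:
        raise DegenerateInputError("zero dynamic range inside the ROI (p1 == p99)")
    out = (np.clip(box, p1, p99) - p1) / (p99 - p1)
    affine = vol.affine.copy()
    affine[:3, 3] = vol.affine[:3, :3] @ lo + vol.affine[:3, 3]
    return ImageVolume(out, affine, vol.modality_tag)
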