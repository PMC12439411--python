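"""End-to-end orchestration: ingest -> reconstruct -> harmonize -> segment ->
post-process -> map back to the original slice geometry.

The whole non-neural pipeline is deterministic: identical inputs, config
and seed produce byte-identical masks.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .dicom_ingest import PlaneStack, load_study
from .errors import ConfigurationError, VetbrainError
from .geometry import BrainMask, ImageVolume, load_mask, save_nifti
from .harmonization import BiasCorrectionParams, bias_correct, zscore
from .mask_remap import map_to_original
from .reconstruction import CanonicalStudy, reconstruct
from .segmentation import (
    ExternalCommandBackend,
    IntensityBandBackend,
    SegmentationBackend,
    postprocess,
    segment,
)
from . import evaluation

__all__ = ["ExtractionResult", "run_study", "extract", "evaluate_directories", "backend_from_config"]

log = logging.getLogger(__name__)


@dataclass
class ExtractionResult:
    """Everything the pipeline produced for one study."""

    canonical_mask: BrainMask
    per_plane_masks: dict[str, BrainMask]
    study: CanonicalStudy
    timings_s: dict[str, float] = field(default_factory=dict)


def backend_from_config(cfg: PipelineConfig) -> SegmentationBackend:
    spec = cfg.require_backend()
    kind = spec["kind"]
    if kind == "intensity-band":
        return IntensityBandBackend(
            low=float(spec["low"]), high=float(spec["high"]),
            quantiles=bool(spec.get("quantiles", False)),
        )
    if kind == "external-command":
        return ExternalCommandBackend(
            command_template=spec["command"], timeout=float(spec.get("timeout", 600.0)),
        )
    raise ConfigurationError(f"unknown backend kind {kind!r}")


def run_study(
    stacks: list[PlaneStack],
    backend: SegmentationBackend,
    cfg: PipelineConfig | None = None,
) -> ExtractionResult:
    """Run the full pipeline on already-ingested plane stacks."""
    cfg = cfg or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    study = reconstruct(
        stacks, side=cfg.side,
        offset_threshold_mm=cfg.offset_threshold_mm,
        overlap_threshold=cfg.overlap_threshold,
    )
    timings["reconstruct"] = time.perf_counter() - t0

    params = BiasCorrectionParams(
        shrink_factor=cfg.shrink_factor, mask_percentile=cfg.mask_percentile
    )

    def _segment_one(vol: ImageVolume) -> BrainMask:
        harmonized = zscore(bias_correct(vol, params))
        return postprocess(segment(harmonized, backend), cfg.center_radius_mm)

    t0 = time.perf_counter()
    canonical_mask = _segment_one(study.fused)
    timings["harmonize+segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    per_plane: dict[str, BrainMask] = {}
    flagged_masks = {
        plane: _segment_one(vol) for plane, vol in study.flagged_planes.items()
    }
    for plane, (affine, shape) in study.per_plane_originals.items():
        source = flagged_masks.get(plane, canonical_mask)
        per_plane[plane] = map_to_original(source, affine, shape)
    timings["map_to_original"] = time.perf_counter() - t0

    return ExtractionResult(canonical_mask, per_plane, study, timings)


def extract(input_dir, config_path, out_dir) -> ExtractionResult:
    """File-level entry point: DICOM study directory in, mask files out."""
    cfg = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()
    backend = backend_from_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    stacks = load_study(input_dir)
    result = run_study(stacks, backend, cfg)
    result.timings_s["ingest"] = time.perf_counter() - t0 - sum(result.timings_s.values())

    save_nifti(result.canonical_mask, out / "mask_canonical.nii.gz")
    for plane, mask in result.per_plane_masks.items():
        save_nifti(mask, out / f"mask_{plane}.nii.gz")
    report = {
        "reference_plane": result.study.reference_plane,
        "alignment_reports": [r.to_dict() for r in result.study.reports],
        "per_plane_originals": {
            p: {"affine": aff.tolist(), "shape": list(shape)}
            for p, (aff, shape) in result.study.per_plane_originals.items()
        },
        "timings_s": result.timings_s,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return result


def evaluate_directories(pred_dir, truth_dir) -> tuple[list[dict], dict]:
    """Score matching mask files of two directories; robust to bad pairs."""
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    rows: list[dict] = []
    names = sorted(p.name for p in pred_dir.iterdir() if p.name.endswith((".nii", ".nii.gz")))
    truth_names = {p.name for p in truth_dir.iterdir()}
    for name in names:
        row: dict = {"case": name}
        if name not in truth_names:
            row["error"] = "missing ground truth"
            rows.append(row)
            continue
        try:
            s = evaluation.score(load_mask(pred_dir / name), load_mask(truth_dir / name))
            row.update(s.to_dict())
        except VetbrainError as exc:
            row["error"] = str(exc)
        rows.append(row)
    ok = [r for r in rows if "error" not in r]
    summary = {}
    for metric in ("dice", "iou", "sensitivity", "specificity"):
        vals = np.array([r[metric] for r in ok]) if ok else np.array([])
        summary[metric] = {
            "mean": float(vals.mean()) if vals.size else float("nan"),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        }
    return rows, summary
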