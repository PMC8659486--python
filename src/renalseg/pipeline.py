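"""End-to-end orchestration: localise -> segment -> compartments -> curves.

The pipeline consumes a YAML/dict config, runs per case, and writes the
compartment label volume, the time-intensity curve table and (when ground
truth is supplied) an evaluation report, together with a reproducibility
manifest (seed, config hash, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .compartments import CompartmentParams, segment_compartments
from .curves import curves_to_frame, extract_curves
from .localizer import load_localizer, predict_boxes
from .metrics import score_labels
from .segmenter import load_segmenter, predict_kidney_mask
from .volumes import (
    BoundingBox3D,
    KidneyMask,
    compute_bounding_box,
    read_dce,
    read_labels,
    read_mask,
    write_labels,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    series: list[str] = field(default_factory=list)
    output_dir: str = "renalseg_out"
    localizer_checkpoint: str | None = None
    segmenter_checkpoint: str | None = None
    use_truth_masks: bool = False
    truth_mask_dir: str | None = None
    truth_label_dir: str | None = None
    compartment_params: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _truth_masks(cfg: PipelineConfig, case: str) -> list[KidneyMask]:
    mask_dir = Path(cfg.truth_mask_dir)
    masks = []
    for side in ("left", "right"):
        matches = sorted(mask_dir.glob(f"{case}_{side}.nii*"))
        if matches:
            masks.append(read_mask(matches[0], side=side))
    if not masks:
        matches = sorted(mask_dir.glob(f"{case}.nii*"))
        if matches:
            masks.append(read_mask(matches[0], side="both"))
    if not masks:
        raise FileNotFoundError(f"no truth masks found for case {case} in {mask_dir}")
    return masks


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run the full per-case pipeline; returns a manifest of outputs."""
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(config)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = CompartmentParams(**cfg.compartment_params)

    localizer_model = segmenter_model = None
    if not cfg.use_truth_masks:
        if not cfg.localizer_checkpoint or not cfg.segmenter_checkpoint:
            raise ValueError(
                "no trained checkpoints configured: set localizer_checkpoint and "
                "segmenter_checkpoint, or use_truth_masks: true for a rule-only run"
            )
        localizer_model = load_localizer(cfg.localizer_checkpoint)
        segmenter_model = load_segmenter(cfg.segmenter_checkpoint)

    case_reports = {}
    for series_path in cfg.series:
        series_path = Path(series_path)
        case = series_path.name.split(".")[0]
        logger.info("case %s: reading %s", case, series_path)
        series = read_dce(series_path)

        if cfg.use_truth_masks:
            masks = _truth_masks(cfg, case)
            boxes = {m.side: compute_bounding_box(m) for m in masks}
        else:
            left_box, right_box = predict_boxes(localizer_model, series, **cfg.preprocess)
            boxes = {"left": left_box, "right": right_box}
            masks = []
            for side, box in boxes.items():
                if not box.present:
                    logger.info("case %s: %s kidney absent", case, side)
                    continue
                masks.append(
                    predict_kidney_mask(segmenter_model, series, box, side=side, **cfg.preprocess)
                )

        labels = segment_compartments(series, masks, params)
        label_path = out_dir / f"{case}_medcor.nii.gz"
        write_labels(labels, label_path, spacing=series.spacing)

        side_masks = {m.side: m for m in masks if m.side in ("left", "right")}
        curve_list = extract_curves(
            series, labels, side_masks=side_masks or None,
            sides=tuple(side_masks) or ("left", "right"),
        )
        curve_path = out_dir / f"{case}_curves.csv"
        curves_to_frame(curve_list).to_csv(curve_path, index=False)

        report = {
            "labels": str(label_path),
            "curves": str(curve_path),
            "kidneys_present": {
                side: bool(box.present) for side, box in boxes.items()
            },
        }
        if cfg.truth_label_dir:
            matches = sorted(Path(cfg.truth_label_dir).glob(f"{case}.nii*"))
            if matches:
                truth = read_labels(matches[0]).data
                report["scores"] = score_labels(truth, labels.data)
        case_reports[case] = report

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "cases": case_reports,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
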