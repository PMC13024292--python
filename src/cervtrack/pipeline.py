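"""One-shot pipeline: mean shapes -> tracking -> segments -> pattern -> reports.

Deterministic given its configuration: every stage is seed-free or derives
randomness from explicit config seeds, so reruns produce byte-identical
tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .datamodel import LabelMaskSequence
from .errors import ConfigError, DataError, InsufficientDataError
from .io import write_trace_table
from .mean_shape import MeanShapeConfig, build_mean_shape
from .motion_pattern import (
    SROM_THRESHOLD_DEG,
    build_pattern,
    low_srom_filter,
    pattern_plot_data,
)
from .reliability import segment_icc_table
from .rotation import FitConfig, segment_traces, track_vertebra
from .seg_metrics import evaluate_sequence, metrics_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    pred_masks: Optional[str] = None
    gt_masks: Optional[str] = None
    output_dir: str = "cervtrack-out"
    fit: FitConfig = field(default_factory=FitConfig)
    mean_shape: MeanShapeConfig = field(default_factory=MeanShapeConfig)
    srom_threshold_deg: float = SROM_THRESHOLD_DEG
    phase: Optional[tuple[int, int]] = None
    spacing_mm: Optional[float] = None
    vertebrae: Optional[list[str]] = None  # default: all present except C0
    write_plots: bool = False


@dataclass
class PipelineResult:
    traces: dict
    segments: dict
    pattern: object
    metrics: Optional[list] = None
    reliability: Optional[object] = None
    output_dir: Optional[Path] = None


def _track_sequence(
    seq: LabelMaskSequence, cfg: PipelineConfig
) -> tuple[dict, dict]:
    vertebrae = cfg.vertebrae or [v for v in seq.vertebrae() if v != "C0"]
    traces = {}
    for v in vertebrae:
        try:
            shape = build_mean_shape(seq, v, cfg.mean_shape)
        except InsufficientDataError:
            continue
        traces[v] = track_vertebra(seq, shape, cfg.fit)
    if not traces:
        raise DataError("no vertebra could be tracked")
    segments = segment_traces(traces, cfg.fit.sigma_frames)
    return traces, segments


def run_pipeline(
    cfg: PipelineConfig,
    pred: Optional[LabelMaskSequence] = None,
    gt: Optional[LabelMaskSequence] = None,
) -> PipelineResult:
    """Run the full analysis; sequences may be passed directly or via paths."""
    from .io import read_mask_sequence

    if pred is None:
        if cfg.pred_masks is None:
            raise ConfigError("no predicted mask stack configured")
        pred = read_mask_sequence(cfg.pred_masks)
    if gt is None and cfg.gt_masks is not None:
        gt = read_mask_sequence(cfg.gt_masks)
    if cfg.spacing_mm is not None:
        pred.meta.pixel_spacing_mm = cfg.spacing_mm
        if gt is not None:
            gt.meta.pixel_spacing_mm = cfg.spacing_mm

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    traces, segments = _track_sequence(pred, cfg)
    write_trace_table(list(traces.values()), out / "vertebra_traces.tsv")
    write_trace_table(list(segments.values()), out / "segment_traces.tsv")

    pattern = build_pattern(list(segments.values()), cfg.phase)
    pattern_plot_data(pattern).to_csv(out / "pattern.tsv", sep="\t", index=False)
    if cfg.write_plots:
        from .motion_pattern import render_pattern

        render_pattern(pattern, out / "pattern.png")

    retained, excluded = low_srom_filter(
        list(segments.values()), cfg.srom_threshold_deg
    )

    metrics = None
    reliability = None
    if gt is not None:
        metrics = evaluate_sequence(pred, gt)
        metrics_table(metrics).to_csv(out / "seg_metrics.tsv", sep="\t", index=False)
        gt_traces, gt_segments = _track_sequence(gt, cfg)
        common = sorted(set(segments) & set(gt_segments))
        rec = pred.meta.recording_id
        reliability = segment_icc_table(
            {rec: {s: segments[s] for s in common}},
            {rec: {s: gt_segments[s] for s in common}},
            srom_threshold_deg=cfg.srom_threshold_deg,
        )
        reliability.per_segment.to_csv(out / "icc.tsv", sep="\t", index=False)

    log = {
        "version": __version__,
        "config": _config_dict(cfg),
        "n_frames": pred.n_frames,
        "vertebrae_tracked": sorted(traces),
        "segments": sorted(segments),
        "ssc": pattern.ssc,
        "srom_deg": {s: segments[s].srom_deg for s in segments},
        "srom_retained": [tr.name for tr in retained],
        "srom_excluded": [[tr.name, reason] for tr, reason in excluded],
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return PipelineResult(
        traces=traces,
        segments=segments,
        pattern=pattern,
        metrics=metrics,
        reliability=reliability,
        output_dir=out,
    )


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    return clean(d)
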