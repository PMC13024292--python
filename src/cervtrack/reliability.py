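"""Agreement statistics between predicted and reference segment traces.

ICC(3,1): single-rater intraclass correlation from a two-way mixed-effects
model under a consistency definition, ``(MS_R − MS_E) / (MS_R + (k−1)·MS_E)``
with the standard F-based 95% confidence interval.  Consistency means the
statistic ignores additive rater offsets.  Values above 0.6 are flagged
acceptable and above 0.8 excellent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import SegmentTrace
from .errors import DataError, InsufficientDataError
from .motion_pattern import low_srom_filter
from .seg_metrics import SegMetricsResult

__all__ = [
    "ICCResult",
    "icc_3_1",
    "ReliabilityReport",
    "segment_icc_table",
    "metric_icc_correlation",
    "ICC_ACCEPTABLE",
    "ICC_EXCELLENT",
]

ICC_ACCEPTABLE = 0.6
ICC_EXCELLENT = 0.8


@dataclass
class ICCResult:
    segment: str
    icc: float
    ci_low: float
    ci_high: float
    n_frames: int
    model: str = "ICC(3,1) consistency"

    @property
    def acceptable(self) -> bool:
        return self.icc > ICC_ACCEPTABLE

    @property
    def excellent(self) -> bool:
        return self.icc > ICC_EXCELLENT


def icc_3_1(
    x: np.ndarray,
    y: np.ndarray,
    segment: str = "",
    alpha: float = 0.05,
) -> ICCResult:
    """ICC(3,1) between two paired series (two raters, consistency).

    Frames missing in either series are dropped; at least 3 complete pairs
    are required.  Zero between-target variance makes the statistic
    undefined (NaN with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("paired series must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"ICC needs >= 3 complete pairs, got {n}")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0:
        warnings.warn("zero between-target variance: ICC undefined")
        return ICCResult(segment, float("nan"), float("nan"), float("nan"), n)
    if ms_e <= 1e-12 * ms_r:  # cancellation noise of the sums of squares
        return ICCResult(segment, 1.0, 1.0, 1.0, n)
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    f_obs = ms_r / ms_e
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_u = stats.f.ppf(1 - alpha / 2, df1, df2)
    f_l_crit = stats.f.ppf(1 - alpha / 2, df2, df1)
    fl = f_obs / f_u
    fu = f_obs * f_l_crit
    ci_low = (fl - 1) / (fl + (k - 1))
    ci_high = (fu - 1) / (fu + (k - 1))
    return ICCResult(segment, float(icc), float(ci_low), float(ci_high), n)


@dataclass
class ReliabilityReport:
    """Per-segment ICC summaries across recordings, after optional filters."""

    per_segment: pd.DataFrame  # segment, icc_mean, icc_min, icc_max, n
    per_recording: pd.DataFrame  # recording, segment, icc, ci_low, ci_high, n_frames
    filters_applied: frozenset = frozenset()
    excluded: list[tuple[str, str, str]] = field(default_factory=list)
    metric_correlations: Optional[pd.DataFrame] = None


def segment_icc_table(
    pred: dict[str, dict[str, SegmentTrace]],
    gt: dict[str, dict[str, SegmentTrace]],
    filters: frozenset | set = frozenset(),
    srom_threshold_deg: float = 4.0,
    quality: Optional[dict[str, dict[str, str]]] = None,
    use_cumulative: bool = False,
) -> ReliabilityReport:
    """Per-segment ICC between predicted and reference traces across recordings.

    ``pred`` and ``gt`` map recording id -> segment name -> trace, with
    matching keys.  ICC is computed per recording per segment on the smoothed
    relative-rotation series (or its cumulative sum with ``use_cumulative``),
    then summarized as mean and min-max range across recordings.

    ``filters`` may contain ``"low_srom"`` (drop segments whose ground-truth
    sROM is below ``srom_threshold_deg``) and ``"low_quality"`` (drop
    segments flagged low in ``quality``).
    """
    filters = frozenset(filters)
    bad = filters - {"low_srom", "low_quality"}
    if bad:
        raise DataError(f"unknown filters: {sorted(bad)}")
    if set(pred) != set(gt):
        raise DataError(
            f"recording keys differ: only-pred={sorted(set(pred) - set(gt))}, "
            f"only-gt={sorted(set(gt) - set(pred))}"
        )
    rows = []
    excluded: list[tuple[str, str, str]] = []
    for rec in sorted(pred):
        psegs, gsegs = pred[rec], gt[rec]
        if set(psegs) != set(gsegs):
            raise DataError(f"segment keys differ in recording {rec}")
        names = sorted(gsegs)
        if "low_srom" in filters:
            kept, dropped = low_srom_filter(
                [gsegs[s] for s in names], threshold_deg=srom_threshold_deg
            )
            for tr, reason in dropped:
                excluded.append((rec, tr.name, reason))
            names = [tr.name for tr in kept]
        if "low_quality" in filters and quality is not None:
            qmap = quality.get(rec, {})
            low = [s for s in names if qmap.get(s, "normal") == "low"]
            for s in low:
                excluded.append((rec, s, "low_quality"))
            names = [s for s in names if s not in low]
        for s in names:
            a = psegs[s].dtheta_rel_smoothed_deg
            b = gsegs[s].dtheta_rel_smoothed_deg
            if use_cumulative:
                a = psegs[s].cumulative_smoothed()
                b = gsegs[s].cumulative_smoothed()
            res = icc_3_1(a, b, segment=s)
            rows.append(
                {
                    "recording": rec,
                    "segment": s,
                    "icc": res.icc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n_frames": res.n_frames,
                }
            )
    per_rec = pd.DataFrame(
        rows, columns=["recording", "segment", "icc", "ci_low", "ci_high", "n_frames"]
    )
    if len(per_rec):
        summary = (
            per_rec.groupby("segment")["icc"]
            .agg(icc_mean="mean", icc_min="min", icc_max="max", n="count")
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["segment", "icc_mean", "icc_min", "icc_max", "n"])
    return ReliabilityReport(
        per_segment=summary,
        per_recording=per_rec,
        filters_applied=filters,
        excluded=excluded,
    )


def metric_icc_correlation(
    icc_by_recording: dict[str, float],
    metrics_by_recording: dict[str, list[SegMetricsResult]],
) -> pd.DataFrame:
    """Pearson r between per-recording ICC and segmentation-metric statistics.

    For each recording the mean, median and SD of each metric (DSC, IoU,
    HD95) are pooled across vertebrae and frames; each statistic is then
    correlated against the recordings' ICC values.  Two-sided p-values are
    reported but never used to filter.  Constant columns give NaN r with a
    warning.
    """
    recs = sorted(set(icc_by_recording) & set(metrics_by_recording))
    if len(recs) < 3:
        raise InsufficientDataError("need >= 3 recordings with both ICC and metrics")
    icc_vals = np.array([icc_by_recording[r] for r in recs], dtype=float)
    rows = []
    for metric in ("dsc", "iou", "hd95"):
        stat_vals = {"mean": [], "median": [], "sd": []}
        for r in recs:
            pooled = np.concatenate(
                [res.per_frame[metric].to_numpy() for res in metrics_by_recording[r]]
            )
            pooled = pooled[np.isfinite(pooled)]
            stat_vals["mean"].append(np.mean(pooled))
            stat_vals["median"].append(np.median(pooled))
            stat_vals["sd"].append(np.std(pooled, ddof=1))
        for stat, vals in stat_vals.items():
            vals = np.asarray(vals, dtype=float)
            if np.ptp(vals) == 0 or np.ptp(icc_vals) == 0:
                warnings.warn(f"constant column for {metric}/{stat}: r undefined")
                r_val, p_val = float("nan"), float("nan")
            else:
                r_val, p_val = stats.pearsonr(vals, icc_vals)
            rows.append(
                {
                    "metric": metric,
                    "statistic": stat,
                    "r": float(r_val),
                    "p": float(p_val),
                    "n": len(recs),
                }
            )
    return pd.DataFrame(rows)
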