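"""Segmental range of motion, motion-pattern curves and contribution order.

The motion-pattern curve of a segment plots its smoothed per-frame rotation
against the cumulative rotation of C4-C7 (sum of the smoothed relative
rotations of C4-C5, C5-C6 and C6-C7).  The sequence of segmental
contribution (SSC) orders segments by the x-position at which their absolute
contribution peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import SegmentTrace, check_same_frame_count
from .errors import DataError, InsufficientDataError

__all__ = [
    "SROM_THRESHOLD_DEG",
    "segmental_rom",
    "low_srom_filter",
    "MotionPattern",
    "build_pattern",
    "pattern_plot_data",
]

#: Segments with a range of motion below this are excluded in sensitivity runs.
SROM_THRESHOLD_DEG = 4.0

_REQUIRED_SEGMENTS = ("C4-C5", "C5-C6", "C6-C7")


def segmental_rom(trace: SegmentTrace) -> float:
    """Range of motion of one segment: max − min of the cumulative smoothed series."""
    finite = np.isfinite(trace.dtheta_rel_smoothed_deg).sum()
    if finite < 2:
        raise InsufficientDataError(
            f"segment {trace.name}: {finite} non-missing frame(s), need >= 2"
        )
    cum = trace.cumulative_smoothed()
    return float(cum.max() - cum.min())


def low_srom_filter(
    traces: Sequence[SegmentTrace], threshold_deg: float = SROM_THRESHOLD_DEG
) -> tuple[list[SegmentTrace], list[tuple[SegmentTrace, str]]]:
    """Partition traces into retained (sROM >= threshold) and excluded.

    The boundary is strict: a trace is dropped only when its sROM is strictly
    below the threshold.  Excluded entries carry a reason string.
    """
    retained: list[SegmentTrace] = []
    excluded: list[tuple[SegmentTrace, str]] = []
    for tr in traces:
        srom = tr.srom_deg if tr.srom_deg > 0 else segmental_rom(tr)
        if srom < threshold_deg:
            excluded.append(
                (tr, f"sROM {srom:.2f} deg below threshold {threshold_deg:g} deg")
            )
        else:
            retained.append(tr)
    return retained, excluded


@dataclass
class MotionPattern:
    """Per-segment contribution curves on a shared cumulative-rotation axis."""

    segments: list[SegmentTrace]
    cumulative_c4c7_deg: np.ndarray
    curves: dict[str, np.ndarray]  # segment name -> per-frame y values
    ssc: list[str]
    ssc_ties: list[str] = field(default_factory=list)
    extension_phase: tuple[int, int] = (0, 0)


def build_pattern(
    traces: Sequence[SegmentTrace],
    extension_phase: Optional[tuple[int, int]] = None,
) -> MotionPattern:
    """Build the motion pattern from segment traces.

    ``extension_phase`` is a half-open frame interval ``(a, b)``; the default
    is the full recording.  Requires the C4-C5, C5-C6 and C6-C7 traces (other
    segments are carried along for plotting).
    """
    by_name = {tr.name: tr for tr in traces}
    missing = [s for s in _REQUIRED_SEGMENTS if s not in by_name]
    if missing:
        raise DataError(f"missing required segment trace(s): {missing}")
    n = check_same_frame_count(list(traces))
    a, b = extension_phase if extension_phase is not None else (0, n)
    if not (0 <= a < b <= n):
        raise DataError(f"empty or invalid extension phase ({a}, {b}) for {n} frames")

    window = slice(a, b)
    rel = [
        np.nan_to_num(by_name[s].dtheta_rel_smoothed_deg[window], nan=0.0)
        for s in _REQUIRED_SEGMENTS
    ]
    cum = np.cumsum(np.sum(rel, axis=0))
    cum -= cum[0]  # cumulative rotation starts at zero

    curves: dict[str, np.ndarray] = {}
    peaks: dict[str, float] = {}
    peak_frames: dict[str, int] = {}
    order = sorted(by_name, key=lambda s: int(s.split("-")[0][1:]))
    for s in order:
        y = by_name[s].dtheta_rel_smoothed_deg[window]
        curves[s] = y
        mag = np.abs(np.nan_to_num(y, nan=0.0))
        idx = int(np.argmax(mag))
        peak_frames[s] = idx
        peaks[s] = float(cum[idx])
    # order by x-position of the peak; ties (peaks within one frame) broken
    # by anatomical level, cranial first, and flagged
    ssc = sorted(order, key=lambda s: (peaks[s], order.index(s)))
    ties = sorted(
        {
            s
            for i, s1 in enumerate(ssc)
            for s2 in ssc[i + 1 :]
            if abs(peak_frames[s1] - peak_frames[s2]) <= 1
            for s in (s1, s2)
        }
    )
    return MotionPattern(
        segments=list(traces),
        cumulative_c4c7_deg=cum,
        curves=curves,
        ssc=ssc,
        ssc_ties=ties,
        extension_phase=(a, b),
    )


def pattern_plot_data(pattern: MotionPattern) -> pd.DataFrame:
    """Long-format table (segment, x, y) of the motion-pattern curves."""
    rows = []
    x = pattern.cumulative_c4c7_deg
    for seg, y in pattern.curves.items():
        for xi, yi in zip(x, y):
            rows.append({"segment": seg, "x": xi, "y": yi})
    return pd.DataFrame(rows, columns=["segment", "x", "y"])


def render_pattern(pattern: MotionPattern, path) -> None:
    """Write a simple motion-pattern figure (one line per segment)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for seg, y in pattern.curves.items():
        ax.plot(pattern.cumulative_c4c7_deg, y, label=seg)
    ax.set_xlabel("cumulative C4-C7 rotation (deg)")
    ax.set_ylabel("segmental rotation per frame (deg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
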