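"""Frame-wise and per-vertebra segmentation evaluation: DSC, IoU, HD95.

HD95 is the symmetric 95th-percentile boundary distance: the maximum over
both directions of the 95th percentile (linear interpolation between order
statistics) of Euclidean distances from each boundary pixel of one mask to
the nearest boundary pixel of the other.  Boundaries are 8-connected outer
boundary pixels: mask pixels with at least one 4-neighbor outside the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .datamodel import LabelMaskSequence
from .errors import DimensionError

__all__ = [
    "dsc",
    "iou",
    "hd95",
    "boundary_pixels",
    "SegMetricsResult",
    "evaluate_sequence",
    "metrics_table",
    "DSC_THRESHOLD",
    "IOU_THRESHOLD",
    "HD95_THRESHOLD_MM",
]

# acceptability thresholds: mean DSC >= 0.8, mean IoU >= 0.7, mean HD95 < 16 mm
DSC_THRESHOLD = 0.8
IOU_THRESHOLD = 0.7
HD95_THRESHOLD_MM = 16.0

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def _as_bool(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise DimensionError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    a, b = _as_bool(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        warnings.warn("DSC undefined for two empty masks")
        return float("nan")
    return 2.0 * int((a & b).sum()) / (na + nb)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union |A∩B| / |A∪B| (Jaccard index)."""
    a, b = _as_bool(a, b)
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("IoU undefined for two empty masks")
        return float("nan")
    return int((a & b).sum()) / union


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Outer boundary: mask pixels with at least one 4-neighbor outside."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~eroded


def _directed_p95(src_boundary: np.ndarray, dst_boundary: np.ndarray) -> float:
    # exact Euclidean distance transform of the complement of dst boundary
    dist = ndimage.distance_transform_edt(~dst_boundary)
    return float(np.percentile(dist[src_boundary], 95))


def hd95(a: np.ndarray, b: np.ndarray, spacing: Optional[float] = None) -> float:
    """Symmetric 95th-percentile Hausdorff boundary distance.

    Returned in pixels, or in millimetres when ``spacing`` (mm/px) is given.
    Empty input masks give NaN with a warning.
    """
    a, b = _as_bool(a, b)
    if not a.any() or not b.any():
        warnings.warn("HD95 undefined for an empty mask")
        return float("nan")
    ba, bb = boundary_pixels(a), boundary_pixels(b)
    value = max(_directed_p95(ba, bb), _directed_p95(bb, ba))
    return value * spacing if spacing is not None else value


@dataclass
class SegMetricsResult:
    """Per-vertebra evaluation across the frames of one recording."""

    vertebra: str
    per_frame: pd.DataFrame  # columns: frame, dsc, iou, hd95
    hd95_unit: str  # {mm, px}
    excluded_frames: list[int] = field(default_factory=list)
    mean_sd: dict[str, tuple[float, float]] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean_sd:
            self.mean_sd = {
                m: (
                    float(self.per_frame[m].mean()),
                    float(self.per_frame[m].std(ddof=1))
                    if len(self.per_frame) > 1
                    else 0.0,
                )
                for m in ("dsc", "iou", "hd95")
            }
        if not self.flags:
            hd_mean = self.mean_sd["hd95"][0]
            self.flags = {
                "dsc_ok": bool(self.mean_sd["dsc"][0] >= DSC_THRESHOLD),
                "iou_ok": bool(self.mean_sd["iou"][0] >= IOU_THRESHOLD),
                "hd95_ok": bool(
                    self.hd95_unit == "mm" and hd_mean < HD95_THRESHOLD_MM
                ),
            }


def evaluate_sequence(
    pred: LabelMaskSequence, gt: LabelMaskSequence
) -> list[SegMetricsResult]:
    """Evaluate a predicted stack against ground truth, per vertebra.

    Frames where either mask is empty for a vertebra are excluded from
    aggregation and listed in ``excluded_frames``.  HD95 is converted to mm
    when the ground-truth metadata carries a pixel spacing; otherwise it is
    reported in pixels and flagged via ``hd95_unit``.
    """
    if pred.n_frames != gt.n_frames:
        raise DimensionError(
            f"frame counts differ: pred {pred.n_frames} vs gt {gt.n_frames}"
        )
    if pred.shape != gt.shape:
        raise DimensionError("frame dimensions differ between pred and gt")
    spacing = gt.meta.pixel_spacing_mm or pred.meta.pixel_spacing_mm
    unit = "mm" if spacing is not None else "px"
    vertebrae = sorted(
        set(pred.vertebrae()) | set(gt.vertebrae()),
        key=lambda v: int(v[1:]),
    )
    results = []
    for v in vertebrae:
        if v not in pred.vertebrae() or v not in gt.vertebrae():
            warnings.warn(f"vertebra {v} absent from one of the sequences")
        rows, excluded = [], []
        for t in range(pred.n_frames):
            pm = pred.vertebra_mask(t, v) if v in pred.label_map.values() else None
            gm = gt.vertebra_mask(t, v) if v in gt.label_map.values() else None
            if pm is None or gm is None or not pm.any() or not gm.any():
                excluded.append(t)
                continue
            rows.append(
                {
                    "frame": t,
                    "dsc": dsc(pm, gm),
                    "iou": iou(pm, gm),
                    "hd95": hd95(pm, gm, spacing=spacing),
                }
            )
        per_frame = pd.DataFrame(rows, columns=["frame", "dsc", "iou", "hd95"])
        results.append(
            SegMetricsResult(
                vertebra=v,
                per_frame=per_frame,
                hd95_unit=unit,
                excluded_frames=excluded,
            )
        )
    return results


def metrics_table(results: list[SegMetricsResult]) -> pd.DataFrame:
    """Mean ± SD summary table, one row per vertebra."""
    rows = []
    for r in results:
        row = {"vertebra": r.vertebra, "n_frames": len(r.per_frame)}
        for m in ("dsc", "iou", "hd95"):
            mean, sd = r.mean_sd[m]
            row[f"{m}_mean"] = mean
            row[f"{m}_sd"] = sd
        row["hd95_unit"] = r.hd95_unit
        row.update(r.flags)
        rows.append(row)
    return pd.DataFrame(rows)
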