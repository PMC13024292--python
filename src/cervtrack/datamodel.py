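"""Core recording data model.

Conventions used throughout the package (stated once, used everywhere):

* images are row-major 2D arrays, origin top-left, 0-based indices;
  ``x`` is the column coordinate and ``y`` the row coordinate;
* angles are in degrees, positive = counter-clockwise in image coordinates;
* label 0 is background; vertebra labels are positive integers mapped to
  names ``C0`` .. ``C7``;
* frame order is acquisition order (the time axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DimensionError, FormatError, InsufficientDataError

__all__ = [
    "VERTEBRA_NAMES",
    "SEGMENT_NAMES",
    "DEFAULT_LABEL_MAP",
    "segment_name",
    "RecordingMeta",
    "LabelMaskSequence",
    "RotationTrace",
    "SegmentTrace",
]

VERTEBRA_NAMES = tuple(f"C{i}" for i in range(8))

#: Adjacent-vertebra motion segments, cranial to caudal.
SEGMENT_NAMES = tuple(f"C{i}-C{i + 1}" for i in range(7))

#: Default label convention: label 1 is the skull base C0, label 8 is C7.
DEFAULT_LABEL_MAP = {i + 1: VERTEBRA_NAMES[i] for i in range(8)}


def segment_name(upper: str, lower: str) -> str:
    """Canonical name of the motion segment between two adjacent vertebrae."""
    return f"{upper}-{lower}"


@dataclass
class RecordingMeta:
    """Per-recording acquisition metadata.

    ``pixel_spacing_mm`` may be absent, in which case boundary distances are
    reported in pixels and flagged as such downstream.
    """

    recording_id: str = "recording"
    frame_rate_hz: float = 15.0
    pixel_spacing_mm: Optional[float] = None
    width_px: int = 0
    height_px: int = 0
    quality_flag: str = "normal"  # {normal, low}
    segment_quality: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_spacing_mm is not None and self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive when given")
        if self.quality_flag not in ("normal", "low"):
            raise ValueError("quality_flag must be 'normal' or 'low'")

    def to_dict(self) -> dict:
        d = {
            "recording_id": self.recording_id,
            "frame_rate_hz": float(self.frame_rate_hz),
            "width_px": int(self.width_px),
            "height_px": int(self.height_px),
            "quality_flag": self.quality_flag,
        }
        if self.pixel_spacing_mm is not None:
            d["pixel_spacing_mm"] = float(self.pixel_spacing_mm)
        if self.segment_quality:
            d["segment_quality"] = dict(self.segment_quality)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        return cls(
            recording_id=d.get("recording_id", "recording"),
            frame_rate_hz=float(d.get("frame_rate_hz", 15.0)),
            pixel_spacing_mm=d.get("pixel_spacing_mm"),
            width_px=int(d.get("width_px", 0)),
            height_px=int(d.get("height_px", 0)),
            quality_flag=d.get("quality_flag", "normal"),
            segment_quality=d.get("segment_quality"),
        )


@dataclass
class LabelMaskSequence:
    """Ordered stack of 2D integer label images plus metadata.

    Every nonzero label present in any frame must appear in ``label_map``.
    """

    meta: RecordingMeta
    frames: list[np.ndarray]
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise InsufficientDataError(
                f"a mask sequence needs >= 2 frames, got {len(self.frames)}"
            )
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if not np.issubdtype(np.asarray(f).dtype, np.integer):
                raise FormatError(f"frame {i} has non-integer dtype {f.dtype}")
            if f.shape != shape:
                raise DimensionError(
                    f"frame {i} shape {f.shape} differs from frame 0 shape {shape}"
                )
        present = set()
        for f in self.frames:
            present.update(np.unique(f).tolist())
        present.discard(0)
        unknown = present - set(self.label_map)
        if unknown:
            raise FormatError(f"labels {sorted(unknown)} missing from label_map")
        self.meta.height_px, self.meta.width_px = shape

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def label_of(self, vertebra: str) -> int:
        for lbl, name in self.label_map.items():
            if name == vertebra:
                return lbl
        raise KeyError(f"vertebra {vertebra!r} not in label_map")

    def vertebra_mask(self, frame_index: int, vertebra: str) -> np.ndarray:
        """Binary mask of one vertebra in one frame."""
        return self.frames[frame_index] == self.label_of(vertebra)

    def vertebrae(self) -> list[str]:
        """Vertebra names actually present (nonempty in >= 1 frame), cranio-caudal."""
        present = set()
        for f in self.frames:
            present.update(int(v) for v in np.unique(f) if v != 0)
        names = {self.label_map[l] for l in present}
        return [v for v in VERTEBRA_NAMES if v in names]

    def to_array(self) -> np.ndarray:
        return np.stack(self.frames, axis=0)


@dataclass
class RotationTrace:
    """Per-frame absolute angle of one vertebra and its frame-to-frame deltas.

    ``theta_deg[t]`` is the fitted absolute angle; missing frames hold NaN and
    are listed in ``missing_frames``.  ``dtheta_deg[0]`` is 0 by convention and
    ``dtheta_deg[t] = theta_deg[t] - theta_deg[t-1]`` whenever both frames were
    fitted.
    """

    vertebra: str
    theta_deg: np.ndarray
    dtheta_deg: np.ndarray
    fit_overlap: np.ndarray
    missing_frames: list[int] = field(default_factory=list)
    low_confidence_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.dtheta_deg = np.asarray(self.dtheta_deg, dtype=float)
        self.fit_overlap = np.asarray(self.fit_overlap, dtype=float)
        n = len(self.theta_deg)
        if len(self.dtheta_deg) != n or len(self.fit_overlap) != n:
            raise DimensionError("theta, dtheta and fit_overlap must share length")

    @property
    def n_frames(self) -> int:
        return len(self.theta_deg)


@dataclass
class SegmentTrace:
    """Relative rotation between two adjacent vertebrae over a recording."""

    upper: str
    lower: str
    dtheta_rel_deg: np.ndarray
    dtheta_rel_smoothed_deg: np.ndarray
    sigma: float = 3.0
    srom_deg: float = 0.0

    def __post_init__(self) -> None:
        self.dtheta_rel_deg = np.asarray(self.dtheta_rel_deg, dtype=float)
        self.dtheta_rel_smoothed_deg = np.asarray(
            self.dtheta_rel_smoothed_deg, dtype=float
        )
        if len(self.dtheta_rel_deg) != len(self.dtheta_rel_smoothed_deg):
            raise DimensionError("raw and smoothed series must share length")
        if self.srom_deg < 0:
            raise ValueError("srom_deg must be nonnegative")

    @property
    def name(self) -> str:
        return segment_name(self.upper, self.lower)

    @property
    def n_frames(self) -> int:
        return len(self.dtheta_rel_deg)

    def cumulative_smoothed(self) -> np.ndarray:
        """Cumulative smoothed relative rotation, NaNs treated as zero motion."""
        d = np.nan_to_num(self.dtheta_rel_smoothed_deg, nan=0.0)
        return np.cumsum(d)


def check_same_frame_count(traces: Sequence) -> int:
    """Return the shared frame count of a set of traces, or raise."""
    if not traces:
        return 0
    counts = {t.n_frames for t in traces}
    if len(counts) != 1:
        raise DimensionError(f"traces have mixed frame counts: {sorted(counts)}")
    return counts.pop()
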