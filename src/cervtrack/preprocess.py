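"""Contrast preprocessing of grayscale frame stacks.

Two operators are provided: histogram equalization restricted to a patient
mask, and histogram matching of every frame to a reference frame (used for
collimated recordings where the black border would dominate the histogram).
Both remappings are monotone in input intensity and neither changes image
dimensions nor pixels outside the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .datamodel import RecordingMeta
from .errors import DegenerateInputError, DimensionError

__all__ = [
    "GrayscaleSequence",
    "patient_mask",
    "equalize_within_mask",
    "match_to_reference",
    "intensity_range_of",
]


def intensity_range_of(frame: np.ndarray) -> tuple[int, int]:
    """Nominal intensity range implied by the dtype (0-255 or 0-65535)."""
    if np.issubdtype(frame.dtype, np.integer):
        info = np.iinfo(frame.dtype)
        return int(info.min), int(info.max)
    return 0, 255


@dataclass
class GrayscaleSequence:
    """Ordered stack of scalar-intensity frames on a stated integer range."""

    meta: RecordingMeta
    frames: list[np.ndarray]
    intensity_range: tuple[int, int] = field(default=(0, 255))

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty frame list")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise DimensionError(f"frame {i} shape mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _n_bins(lo: int, hi: int) -> int:
    return 256 if hi - lo <= 255 else 1024


def patient_mask(
    frame: np.ndarray,
    threshold: str | float = "otsu",
) -> np.ndarray:
    """Binary mask of the patient region of one frame.

    Thresholds the frame (Otsu by default, or a fixed value), keeps the
    largest connected foreground component, and fills holes, so that air and
    collimator borders are excluded.  An all-background frame yields a zero
    mask with a warning.  A frame with no intensity variation is taken as all
    foreground (nothing to exclude).
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if not np.any(frame):
        warnings.warn("all-zero frame: returning empty patient mask")
        return np.zeros(frame.shape, dtype=bool)
    if frame.min() == frame.max():
        return np.ones(frame.shape, dtype=bool)
    if threshold == "otsu":
        thr = threshold_otsu(frame)
    else:
        thr = float(threshold)
    fg = frame > thr
    if not fg.any():
        warnings.warn("threshold left no foreground: returning empty patient mask")
        return np.zeros(frame.shape, dtype=bool)
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(fg)


def _masked_cdf(values: np.ndarray, lo: int, hi: int, bins: int):
    hist, edges = np.histogram(values, bins=bins, range=(lo, hi + 1))
    cdf = np.cumsum(hist).astype(float)
    cdf /= cdf[-1]
    return cdf, edges


def equalize_within_mask(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Histogram-equalize the pixels inside ``mask``; leave the rest untouched.

    The mapping sends intensity ``v`` to ``round(cdf(v) * hi)`` where the CDF
    is computed from masked pixels only and ``hi`` is the top of the dtype
    range.  Output dtype and range equal the input's.
    """
    frame = np.asarray(frame)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape:
        raise DimensionError("mask shape must match frame shape")
    if not mask.any():
        warnings.warn("empty mask: frame returned unchanged")
        return frame.copy()
    lo, hi = intensity_range_of(frame)
    bins = _n_bins(lo, hi)
    vals = frame[mask]
    cdf, edges = _masked_cdf(vals, lo, hi, bins)
    bin_idx = np.clip(
        np.digitize(vals, edges[1:-1], right=False), 0, bins - 1
    )
    mapped = np.rint(cdf[bin_idx] * hi).astype(frame.dtype)
    out = frame.copy()
    out[mask] = mapped
    return out


def _match_lut(src_vals: np.ndarray, ref_vals: np.ndarray, lo: int, hi: int):
    """Monotone lookup table mapping source intensities onto the reference CDF."""
    bins = _n_bins(lo, hi)
    src_cdf, edges = _masked_cdf(src_vals, lo, hi, bins)
    ref_cdf, _ = _masked_cdf(ref_vals, lo, hi, bins)
    centers = edges[:-1]
    # smallest reference intensity whose CDF reaches the source CDF
    idx = np.searchsorted(ref_cdf, src_cdf - 1e-12, side="left")
    idx = np.clip(idx, 0, bins - 1)
    return centers, np.rint(centers[idx]).astype(int)


def match_to_reference(
    seq: GrayscaleSequence, reference: np.ndarray
) -> GrayscaleSequence:
    """Map each frame's intensity CDF onto a reference frame's CDF.

    The per-frame lookup is monotone; a frame already equal to the reference
    comes back unchanged up to quantization.
    """
    reference = np.asarray(reference)
    if reference.size == 0:
        raise ValueError("empty reference")
    if reference.min() == reference.max():
        raise DegenerateInputError("constant reference image cannot anchor a CDF")
    lo, hi = seq.intensity_range
    out_frames = []
    for f in seq.frames:
        centers, lut_vals = _match_lut(f.ravel(), reference.ravel(), lo, hi)
        bins = len(centers)
        edges = np.linspace(lo, hi + 1, bins + 1)
        bin_idx = np.clip(np.digitize(f, edges[1:-1], right=False), 0, bins - 1)
        out_frames.append(np.clip(lut_vals[bin_idx], lo, hi).astype(f.dtype))
    return GrayscaleSequence(
        meta=seq.meta, frames=out_frames, intensity_range=seq.intensity_range
    )


def equalize_sequence(
    seq: GrayscaleSequence,
    threshold: str | float = "otsu",
    global_mapping: bool = False,
    mask: Optional[np.ndarray] = None,
) -> GrayscaleSequence:
    """Apply masked equalization per frame (default) or with one global mapping.

    With ``global_mapping`` the CDF is pooled over all frames' masked pixels
    and the same lookup applied to every frame.
    """
    masks = (
        [np.asarray(mask, dtype=bool)] * seq.n_frames
        if mask is not None
        else [patient_mask(f, threshold) for f in seq.frames]
    )
    if not global_mapping:
        frames = [equalize_within_mask(f, m) for f, m in zip(seq.frames, masks)]
        return GrayscaleSequence(
            meta=seq.meta, frames=frames, intensity_range=seq.intensity_range
        )
    lo, hi = seq.intensity_range
    bins = _n_bins(lo, hi)
    pooled = np.concatenate(
        [f[m] for f, m in zip(seq.frames, masks) if m.any()] or [np.array([lo])]
    )
    cdf, edges = _masked_cdf(pooled, lo, hi, bins)
    frames = []
    for f, m in zip(seq.frames, masks):
        out = f.copy()
        if m.any():
            vals = f[m]
            bin_idx = np.clip(np.digitize(vals, edges[1:-1], right=False), 0, bins - 1)
            out[m] = np.rint(cdf[bin_idx] * hi).astype(f.dtype)
        frames.append(out)
    return GrayscaleSequence(
        meta=seq.meta, frames=frames, intensity_range=seq.intensity_range
    )
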