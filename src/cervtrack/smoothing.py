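"""Gaussian low-pass smoothing of rotation time series.

Discrete Gaussian convolution (kernel ``exp(-i²/2σ²)`` truncated at 4σ and
normalized to unit sum, i.e. unit DC gain) with reflective boundary
handling.  Missing values are linearly interpolated before filtering and
re-flagged afterwards.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DataError

__all__ = ["smooth_trace", "gaussian_kernel"]

_TRUNCATE = 4.0


def gaussian_kernel(sigma: float) -> np.ndarray:
    """The discrete kernel used by :func:`smooth_trace` (unit sum)."""
    radius = int(_TRUNCATE * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_trace(series: np.ndarray, sigma_frames: float = 3.0) -> np.ndarray:
    """Smooth a per-frame series with a Gaussian of width ``sigma_frames``.

    NaNs are interpolated linearly (edge NaNs held at the nearest finite
    value) for the convolution and restored to NaN in the output.  A constant
    series passes through unchanged.
    """
    if sigma_frames <= 0:
        raise ValueError("sigma_frames must be positive")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a nonempty 1D array")
    nan_mask = ~np.isfinite(x)
    if nan_mask.all():
        raise DataError("cannot smooth an all-missing series")
    if nan_mask.any():
        idx = np.arange(x.size)
        x = x.copy()
        x[nan_mask] = np.interp(idx[nan_mask], idx[~nan_mask], x[~nan_mask])
    out = gaussian_filter1d(x, sigma_frames, mode="reflect", truncate=_TRUNCATE)
    out[nan_mask] = np.nan
    return out
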