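"""Per-frame rigid rotation fitting of a vertebra template to label masks.

The template is translated so its centroid coincides with the mask centroid
(sub-pixel), then rotated for maximal overlap.  The angle search is limited
to a window of ±90° around the previous frame's accepted angle, which
prevents half-turn flips between consecutive frames: a coarse scan on a 1°
grid is followed by golden-section refinement of the overlap objective.
Rotated templates are rasterized by bilinear sampling and thresholding at
0.5, which makes every fit deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .datamodel import LabelMaskSequence, RotationTrace, SegmentTrace, segment_name
from .errors import ConfigError, DataError, DimensionError
from .smoothing import smooth_trace

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_angle",
    "track_vertebra",
    "relative_rotation",
    "smooth_trace",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class FitConfig:
    """Parameters of the angle search and trace smoothing."""

    angle_window_deg: float = 90.0
    coarse_step_deg: float = 1.0
    refine_tol_deg: float = 0.01
    overlap_criterion: str = "dice"  # {dice, intersection}
    overlap_floor: float = 0.5
    sigma_frames: float = 3.0
    #: Gaussian blur (px, per side) applied to template and mask inside the
    #: overlap objective; suppresses rasterization jitter of binary boundaries
    #: without moving the optimum of a rigid fit.  0 disables.
    objective_blur_px: float = 1.0
    #: Integer supersampling factor of the refinement grid (1 disables).
    #: Reduces bilinear-interpolation bias of the objective near its optimum.
    refine_supersample: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.coarse_step_deg <= self.angle_window_deg):
            raise ConfigError("need 0 < coarse_step_deg <= angle_window_deg")
        if self.refine_tol_deg <= 0:
            raise ConfigError("refine_tol_deg must be positive")
        if self.overlap_criterion not in ("dice", "intersection"):
            raise ConfigError("overlap_criterion must be 'dice' or 'intersection'")


@dataclass
class FitResult:
    angle_deg: float
    overlap: float
    low_confidence: bool = False
    missing: bool = False


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    ys, xs = np.nonzero(mask)
    return float(ys.mean()), float(xs.mean())


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    # positive angle = counter-clockwise in image coordinates (y down)
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, s], [-s, c]])


class _TemplateFitter:
    """Caches rotated rasterizations of one template for repeated fitting.

    Integer-degree rotations (used by the coarse scan) are cached; the
    golden-section refinement evaluates arbitrary angles with full sub-pixel
    centroid alignment.
    """

    def __init__(self, template: np.ndarray, cfg: FitConfig):
        self.cfg = cfg
        template = np.asarray(template, dtype=float)
        # a float template (occupancy average in [0, 1]) keeps sub-pixel
        # boundary information; a boolean template works identically
        ys, xs = np.nonzero(template > 1e-6)
        if ys.size:
            template = template[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
        # pad so any rotation about the centroid fits in the working window:
        # radius = largest centroid-to-bounding-box-corner distance
        h, w = template.shape
        cy, cx = self._weighted_centroid(template)
        r = int(
            np.ceil(
                max(
                    math.hypot(dy, dx)
                    for dy in (cy, h - 1 - cy)
                    for dx in (cx, w - 1 - cx)
                )
            )
        ) + 2
        self.size = 2 * r + 1
        self.canvas = self._embed(template, r)
        self.center = float(r)
        self.n_template = int((self.canvas >= 0.5).sum())
        self._cache: dict[int, np.ndarray] = {}
        self.ss = max(int(cfg.refine_supersample), 1)
        if self.ss > 1:
            self.canvas_ss = ndimage.zoom(self.canvas, float(self.ss), order=1)
            self.center_ss = (self.canvas_ss.shape[0] - 1) / 2.0
        else:
            self.canvas_ss = self.canvas
            self.center_ss = self.center

    @staticmethod
    def _weighted_centroid(arr: np.ndarray) -> tuple[float, float]:
        total = arr.sum()
        ys, xs = np.nonzero(arr)
        w = arr[ys, xs]
        return float((ys * w).sum() / total), float((xs * w).sum() / total)

    @classmethod
    def _embed(cls, template: np.ndarray, r: int) -> np.ndarray:
        size = 2 * r + 1
        canvas = np.zeros((size, size), dtype=float)
        cy, cx = cls._weighted_centroid(template)
        iy, ix = int(round(r - cy)), int(round(r - cx))
        h, w = template.shape
        canvas[iy : iy + h, ix : ix + w] = template
        # sub-pixel recentring so the canvas centroid sits at the center
        ccy, ccx = cls._weighted_centroid(canvas)
        dy, dx = r - ccy, r - ccx
        if abs(dy) > 1e-9 or abs(dx) > 1e-9:
            canvas = ndimage.shift(canvas, (dy, dx), order=1, mode="constant")
        return canvas

    def _rotated_int(self, angle_deg: int) -> np.ndarray:
        key = int(angle_deg)
        if key not in self._cache:
            self._cache[key] = self._rotate_float(float(key), 0.0, 0.0)
        return self._cache[key]

    def _rotate_float(self, angle_deg: float, dy: float, dx: float) -> np.ndarray:
        """Bilinear rotation of the canvas about its center, shifted by (dy, dx)."""
        rot = _rotation_matrix(-angle_deg)  # inverse map: output -> input
        c = self.center
        offset = np.array([c, c]) - rot @ np.array([c + dy, c + dx])
        return ndimage.affine_transform(
            self.canvas, rot, offset=offset, order=1, mode="constant", cval=0.0,
            output_shape=(self.size, self.size),
        )

    def _refine_crop(self, a_best: float) -> tuple[slice, slice]:
        """Bounding box of the template rotated near ``a_best``, on the ss grid.

        Refinement only explores ±coarse_step around the coarse optimum, so the
        objective can be evaluated on this crop instead of the full canvas.
        """
        rotated = self._rotated_int(int(round(a_best)))
        ys, xs = np.nonzero(rotated > 1e-6)
        # margin: worst-case motion of a boundary pixel under a ±2 deg extra
        # rotation, plus the sub-pixel shift and blur support
        m = int(math.ceil(self.center * math.sin(math.radians(2.0)))) + 4
        n = self.size
        y0, y1 = max(ys.min() - m, 0), min(ys.max() + m + 1, n)
        x0, x1 = max(xs.min() - m, 0), min(xs.max() + m + 1, n)
        s = self.ss
        n_ss = self.canvas_ss.shape[0]
        return (
            slice(s * y0, min(s * y1, n_ss)),
            slice(s * x0, min(s * x1, n_ss)),
        )

    def _rotate_float_ss(
        self, angle_deg: float, dy: float, dx: float, crop: tuple[slice, slice]
    ) -> np.ndarray:
        """Rotation evaluated on a cropped supersampled grid (refinement only)."""
        rot = _rotation_matrix(-angle_deg)
        c = self.center_ss
        s = float(self.ss)
        offset = np.array([c, c]) - rot @ np.array([c + s * dy, c + s * dx])
        cy_sl, cx_sl = crop
        origin = np.array([cy_sl.start, cx_sl.start], dtype=float)
        shape = (cy_sl.stop - cy_sl.start, cx_sl.stop - cx_sl.start)
        return ndimage.affine_transform(
            self.canvas_ss, rot, offset=rot @ origin + offset, order=1,
            mode="constant", cval=0.0, output_shape=shape,
        )

    def _rasterize(self, angle_deg: float, dy: float, dx: float) -> np.ndarray:
        """Rotated template rasterization: bilinear sampling, 0.5 threshold."""
        return self._rotate_float(angle_deg, dy, dx) >= 0.5

    def _window(self, mask: np.ndarray, cy_i: int, cx_i: int) -> np.ndarray:
        """Crop of the mask, centered at integer centroid, canvas-sized."""
        r = int(self.center)
        h, w = mask.shape
        y0, y1 = cy_i - r, cy_i + r + 1
        x0, x1 = cx_i - r, cx_i + r + 1
        win = np.zeros((self.size, self.size), dtype=bool)
        sy0, sy1 = max(y0, 0), min(y1, h)
        sx0, sx1 = max(x0, 0), min(x1, w)
        if sy0 < sy1 and sx0 < sx1:
            win[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = mask[sy0:sy1, sx0:sx1]
        return win

    def _score(self, rotated: np.ndarray, win: np.ndarray, n_mask: int) -> float:
        """Soft overlap of a float (bilinear) rotation against the mask window.

        ``win`` is the (possibly blurred) float mask window.  Unthresholded
        sampling keeps the objective smooth in the angle, which golden-section
        refinement needs; blurring both sides of the product is folded into a
        single blur of the window (convolution associativity).  The reported
        overlap of the accepted fit is the hard DSC of the thresholded
        rasterization.
        """
        inter = float((rotated * win).sum())
        if self.cfg.overlap_criterion == "intersection":
            return inter / max(n_mask, 1)
        denom = float(rotated.sum()) + n_mask
        return 2.0 * inter / denom if denom else 0.0

    def _hard_overlap(self, angle: float, dy: float, dx: float,
                      win: np.ndarray, n_mask: int) -> float:
        rotated = self._rasterize(angle, dy, dx)
        inter = int((rotated & win).sum())
        if self.cfg.overlap_criterion == "intersection":
            return inter / max(n_mask, 1)
        denom = int(rotated.sum()) + n_mask
        return 2.0 * inter / denom if denom else 0.0

    def fit(self, mask: np.ndarray, prev_angle_deg: float) -> FitResult:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return FitResult(float("nan"), float("nan"), missing=True)
        cfg = self.cfg
        cy, cx = _centroid(mask)
        cy_i, cx_i = int(round(cy)), int(round(cx))
        fy, fx = cy - cy_i, cx - cx_i
        win = self._window(mask, cy_i, cx_i)
        n_mask = int(mask.sum())
        if cfg.objective_blur_px > 0:
            winf = ndimage.gaussian_filter(
                win.astype(float), math.sqrt(2.0) * cfg.objective_blur_px
            )
        else:
            winf = win.astype(float)

        lo = prev_angle_deg - cfg.angle_window_deg
        hi = prev_angle_deg + cfg.angle_window_deg
        grid = np.arange(math.ceil(lo), math.floor(hi) + 1, dtype=int)
        if grid.size == 0:
            grid = np.array([int(round(prev_angle_deg))])
        # hierarchical coarse scan: every 5th integer angle across the whole
        # window, then the 1-degree grid around the best; the blurred overlap
        # objective is smooth enough that a 5-degree stride cannot alias
        if grid.size > 25:
            stride = grid[:: max(1, round(5.0 / cfg.coarse_step_deg))]
            s0 = [self._score(self._rotated_int(int(a)), winf, n_mask) for a in stride]
            center = int(stride[int(np.argmax(s0))])
            grid = grid[(grid >= center - 5) & (grid <= center + 5)]
        scores = [self._score(self._rotated_int(int(a)), winf, n_mask) for a in grid]
        best_i = int(np.argmax(scores))
        a_best = float(grid[best_i])

        # golden-section refinement around the best coarse angle, sub-pixel
        # alignment on the cropped supersampled grid
        crop = self._refine_crop(a_best)
        if self.ss > 1:
            winf_ss = ndimage.zoom(winf, float(self.ss), order=1)[crop]
        else:
            winf_ss = winf[crop]

        def objective(angle: float) -> float:
            return self._score(
                self._rotate_float_ss(angle, fy, fx, crop), winf_ss, n_mask
            )

        a_lo = max(a_best - cfg.coarse_step_deg, lo)
        a_hi = min(a_best + cfg.coarse_step_deg, hi)
        x1 = a_hi - _GOLDEN * (a_hi - a_lo)
        x2 = a_lo + _GOLDEN * (a_hi - a_lo)
        f1, f2 = objective(x1), objective(x2)
        while a_hi - a_lo > cfg.refine_tol_deg:
            if f1 < f2:
                a_lo, x1, f1 = x1, x2, f2
                x2 = a_lo + _GOLDEN * (a_hi - a_lo)
                f2 = objective(x2)
            else:
                a_hi, x2, f2 = x2, x1, f1
                x1 = a_hi - _GOLDEN * (a_hi - a_lo)
                f1 = objective(x1)
        angle = float(np.clip(0.5 * (a_lo + a_hi), lo, hi))
        overlap = self._hard_overlap(angle, fy, fx, win, n_mask)
        return FitResult(angle, overlap, low_confidence=overlap < cfg.overlap_floor)


def fit_angle(
    template,
    mask: np.ndarray,
    prev_angle_deg: float = 0.0,
    cfg: Optional[FitConfig] = None,
) -> FitResult:
    """Fit the template to a single mask; see module docstring for the search.

    ``template`` is a ``MeanShape`` or a bare binary array.  An empty mask
    yields a missing-fit marker; an overlap below ``cfg.overlap_floor`` sets
    the low-confidence flag.
    """
    cfg = cfg or FitConfig()
    arr = _template_array(template)
    return _TemplateFitter(arr, cfg).fit(np.asarray(mask), prev_angle_deg)


def _template_array(template) -> np.ndarray:
    """Fitting array of a template: float occupancy if available, else binary."""
    arr = getattr(template, "template_float", None)
    if arr is None:
        arr = getattr(template, "template", template)
    return np.asarray(arr)


def track_vertebra(
    seq: LabelMaskSequence,
    template,
    cfg: Optional[FitConfig] = None,
    vertebra: Optional[str] = None,
) -> RotationTrace:
    """Track one vertebra through the whole recording.

    Frame 0 is fitted with a previous angle of 0; every subsequent frame with
    the previous accepted angle, so no frame-to-frame jump can exceed the
    angle window.  The frame-to-frame delta is zero for the first frame and
    ``theta[t] - theta[t-1]`` thereafter; frames without the label propagate
    the last accepted angle as the search center and are recorded as gaps.
    """
    cfg = cfg or FitConfig()
    name = vertebra or getattr(template, "vertebra", None)
    if name is None:
        raise ConfigError("vertebra name required when template carries none")
    fitter = _TemplateFitter(_template_array(template), cfg)
    n = seq.n_frames
    theta = np.full(n, np.nan)
    overlap = np.full(n, np.nan)
    missing: list[int] = []
    low_conf: list[int] = []
    prev = 0.0
    any_fit = False
    for t in range(n):
        mask = seq.vertebra_mask(t, name)
        res = fitter.fit(mask, prev)
        if res.missing:
            missing.append(t)
            continue
        any_fit = True
        theta[t] = res.angle_deg
        overlap[t] = res.overlap
        if res.low_confidence:
            low_conf.append(t)
        prev = res.angle_deg
    if not any_fit:
        raise DataError(f"vertebra {name}: empty in every frame, no trace")
    dtheta = np.full(n, np.nan)
    dtheta[0] = 0.0
    for t in range(1, n):
        if np.isfinite(theta[t]) and np.isfinite(theta[t - 1]):
            dtheta[t] = theta[t] - theta[t - 1]
    return RotationTrace(
        vertebra=name,
        theta_deg=theta,
        dtheta_deg=dtheta,
        fit_overlap=overlap,
        missing_frames=missing,
        low_confidence_frames=low_conf,
    )


def relative_rotation(
    upper: RotationTrace,
    lower: RotationTrace,
    sigma_frames: float = 3.0,
) -> SegmentTrace:
    """Relative rotation of a motion segment: upper minus lower deltas.

    Frames missing in either trace are missing in the output.  The smoothed
    series and the segmental range of motion (max minus min of the cumulative
    smoothed series) are computed here.
    """
    if upper.n_frames != lower.n_frames:
        raise DimensionError("traces must have equal frame counts")
    rel = upper.dtheta_deg - lower.dtheta_deg
    smoothed = smooth_trace(rel, sigma_frames)
    filled = np.nan_to_num(smoothed, nan=0.0)
    cum = np.cumsum(filled)
    srom = float(cum.max() - cum.min()) if len(cum) else 0.0
    return SegmentTrace(
        upper=upper.vertebra,
        lower=lower.vertebra,
        dtheta_rel_deg=rel,
        dtheta_rel_smoothed_deg=smoothed,
        sigma=sigma_frames,
        srom_deg=srom,
    )


def segment_traces(
    traces: dict[str, RotationTrace], sigma_frames: float = 3.0
) -> dict[str, SegmentTrace]:
    """Build all adjacent-pair segment traces available from vertebra traces."""
    out: dict[str, SegmentTrace] = {}
    for i in range(7):
        up, lo = f"C{i}", f"C{i + 1}"
        if up in traces and lo in traces:
            seg = relative_rotation(traces[up], traces[lo], sigma_frames)
            out[segment_name(up, lo)] = seg
    return out
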