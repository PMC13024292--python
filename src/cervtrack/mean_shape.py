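"""Per-recording rigid mean shape of one vertebra.

The template is built by alternating alignment and averaging: masks are
translated to a common centroid, averaged and thresholded at 0.5 for a
provisional template; each frame's rotation is then re-fitted to the
template, the masks are de-rotated and re-averaged, and the loop repeats
until the mean overlap stabilizes.  The skull base C0 is excluded by default
because of its inconsistent visibility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .datamodel import LabelMaskSequence
from .errors import ConfigError, InsufficientDataError
from .rotation import FitConfig, _TemplateFitter, _centroid, _rotation_matrix

__all__ = ["MeanShape", "MeanShapeConfig", "build_mean_shape", "mean_shape_overlap"]


@dataclass
class MeanShapeConfig:
    min_frames: int = 3
    threshold: float = 0.5
    tol: float = 1e-3  # mean-DSC change for convergence
    max_iter: int = 10
    allow_c0: bool = False
    # supersampled refinement is unnecessary here: per-frame angle noise is
    # averaged out by the mask averaging, so the cheap fit suffices
    fit: FitConfig = field(
        default_factory=lambda: FitConfig(refine_supersample=1)
    )


@dataclass
class MeanShape:
    """Rigid binary template of one vertebra in a local frame.

    The template centroid sits at the array center (within 0.5 px), which is
    the local origin; the zero-angle convention is the template's own
    orientation (``reference_angle_deg`` is 0 by construction).
    """

    vertebra: str
    template: np.ndarray
    centroid: tuple[float, float]
    reference_angle_deg: float = 0.0
    n_frames_used: int = 0
    convergence: list[float] = field(default_factory=list)
    converged: bool = True
    #: float occupancy average behind the binary template; preferred by the
    #: rotation fitter because it keeps sub-pixel boundary information
    template_float: Optional[np.ndarray] = None


def _nonempty_frames(seq: LabelMaskSequence, vertebra: str) -> list[int]:
    label = seq.label_of(vertebra)
    return [t for t in range(seq.n_frames) if np.any(seq.frames[t] == label)]


def _aligned_average(
    seq: LabelMaskSequence,
    vertebra: str,
    frames: list[int],
    angles: dict[int, float],
    size: int,
) -> np.ndarray:
    """Average the masks after removing each frame's translation and rotation."""
    r = size // 2
    acc = np.zeros((size, size), dtype=float)
    for t in frames:
        mask = seq.vertebra_mask(t, vertebra).astype(float)
        cy, cx = _centroid(mask >= 0.5)
        rot = _rotation_matrix(angles.get(t, 0.0))  # de-rotate by fitted angle
        offset = np.array([cy, cx]) - rot @ np.array([r, r])
        aligned = ndimage.affine_transform(
            mask, rot, offset=offset, order=1, mode="constant", cval=0.0,
            output_shape=(size, size),
        )
        acc += aligned
    return acc / len(frames)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _recenter(
    template: np.ndarray, template_float: np.ndarray, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-shift so the binary centroid is within 0.5 px of center."""
    cy, cx = _centroid(template)
    r = size // 2
    dy, dx = int(round(r - cy)), int(round(r - cx))
    if dy or dx:
        template = np.roll(np.roll(template, dy, axis=0), dx, axis=1)
        template_float = np.roll(np.roll(template_float, dy, axis=0), dx, axis=1)
    return template, template_float


def build_mean_shape(
    seq: LabelMaskSequence,
    vertebra: str,
    config: Optional[MeanShapeConfig] = None,
) -> MeanShape:
    """Construct the mean shape of one vertebra from all frames of a recording.

    Raises ``InsufficientDataError`` when the vertebra is nonempty in fewer
    than ``config.min_frames`` frames.  If the iteration fails to converge
    within ``max_iter`` passes the best iterate is returned with
    ``converged=False`` and a warning.
    """
    cfg = config or MeanShapeConfig()
    if vertebra == "C0" and not cfg.allow_c0:
        raise ConfigError(
            "C0 is excluded from mean-shape construction by default "
            "(inconsistent visibility); pass allow_c0=True to override"
        )
    frames = _nonempty_frames(seq, vertebra)
    if len(frames) < cfg.min_frames:
        raise InsufficientDataError(
            f"vertebra {vertebra}: {len(frames)} nonempty frame(s), "
            f"minimum is {cfg.min_frames}"
        )
    # working canvas large enough for any rotation of the largest instance
    max_h = max_w = 0
    label = seq.label_of(vertebra)
    for t in frames:
        ys, xs = np.nonzero(seq.frames[t] == label)
        max_h = max(max_h, ys.max() - ys.min() + 1)
        max_w = max(max_w, xs.max() - xs.min() + 1)
    r = int(math.ceil(0.5 * math.hypot(max_h, max_w))) + 3
    size = 2 * r + 1

    def make_template(angles: dict[int, float]) -> tuple[np.ndarray, np.ndarray]:
        avg = _aligned_average(seq, vertebra, frames, angles, size)
        binary = _largest_component(avg >= cfg.threshold)
        # keep the occupancy average but suppress satellite components
        keep = ndimage.binary_dilation(binary, iterations=2)
        avg = np.where(keep, avg, 0.0)
        binary, avg = _recenter(binary, avg, size)
        return binary, avg

    angles: dict[int, float] = {t: 0.0 for t in frames}
    template, template_float = make_template(angles)
    convergence: list[float] = []
    converged = False
    for _ in range(cfg.max_iter):
        fitter = _TemplateFitter(template_float, cfg.fit)
        overlaps = []
        prev = 0.0
        for t in frames:
            res = fitter.fit(seq.vertebra_mask(t, vertebra), prev)
            angles[t] = res.angle_deg
            prev = res.angle_deg
            overlaps.append(res.overlap)
        mean_overlap = float(np.mean(overlaps))
        if convergence and abs(mean_overlap - convergence[-1]) < cfg.tol:
            convergence.append(mean_overlap)
            converged = True
            break
        convergence.append(mean_overlap)
        template, template_float = make_template(angles)
    if not converged:
        warnings.warn(
            f"mean shape for {vertebra} did not converge in {cfg.max_iter} "
            "iterations; returning best iterate"
        )
    if not template.any():
        raise InsufficientDataError(f"vertebra {vertebra}: empty mean shape")
    cy, cx = _centroid(template)
    return MeanShape(
        vertebra=vertebra,
        template=template,
        centroid=(cx, cy),
        n_frames_used=len(frames),
        convergence=convergence,
        converged=converged,
        template_float=template_float,
    )


def mean_shape_overlap(
    shape: MeanShape,
    seq: LabelMaskSequence,
    vertebra: Optional[str] = None,
    cfg: Optional[FitConfig] = None,
) -> np.ndarray:
    """Per-frame best-fit overlap (DSC) of the template against each mask.

    Frames where the label is empty hold NaN.
    """
    v = vertebra or shape.vertebra
    fit_cfg = cfg or FitConfig()
    arr = shape.template_float if shape.template_float is not None else shape.template
    fitter = _TemplateFitter(arr, fit_cfg)
    out = np.full(seq.n_frames, np.nan)
    prev = 0.0
    for t in range(seq.n_frames):
        res = fitter.fit(seq.vertebra_mask(t, v), prev)
        if not res.missing:
            out[t] = res.overlap
            prev = res.angle_deg
    return out
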