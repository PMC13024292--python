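"""Synthetic dynamic recordings with known ground-truth kinematics.

An articulated 2D chain of rounded-rectangle "vertebrae" (C0 cranial to C7
caudal) performs a smooth extension sweep.  Each motion segment contributes
a programmed angular excursion whose per-frame rate follows a raised-cosine
bump centered at a configurable position of the sweep, so the order of
maximum segmental contribution is known by construction.  The caudal
vertebra C7 is the static reference.  Ground-truth absolute angles are
analytic; masks are rasterized from them, optionally degraded with smooth
boundary jitter, per-label dropout and an occlusion band.  All randomness
derives from the config seed, so output is bit-reproducible.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .datamodel import (
    LabelMaskSequence,
    RecordingMeta,
    RotationTrace,
    SegmentTrace,
    VERTEBRA_NAMES,
    segment_name,
)
from .errors import ConfigError, DataError
from .rotation import _rotation_matrix
from .smoothing import smooth_trace

__all__ = [
    "OcclusionBand",
    "PhantomConfig",
    "PhantomRecording",
    "generate",
    "degrade",
    "render_intensity",
    "DEFAULT_CONTRIBUTIONS",
]

# per-segment (excursion_deg, peak position in [0, 1] of the sweep); sums to 40
DEFAULT_CONTRIBUTIONS: dict[str, tuple[float, float]] = {
    "C0-C1": (3.0, 0.50),
    "C1-C2": (5.0, 0.35),
    "C2-C3": (4.0, 0.45),
    "C3-C4": (4.0, 0.65),
    "C4-C5": (10.0, 0.80),
    "C5-C6": (8.0, 0.50),
    "C6-C7": (6.0, 0.20),
}

# reference geometry at 1024 px image height: (height, width) per level C0..C7
_REF_HEIGHTS = (90, 58, 66, 68, 70, 72, 74, 78)
_REF_WIDTHS = (150, 96, 100, 104, 110, 114, 120, 126)
_REF_GAP = 16
_REF_CORNER = 12
# slight static lordotic posture per segment (deg), constant in time
_POSTURE_DEG = (2.0, 1.5, 1.0, 0.5, -0.5, -1.0, -1.5)


@dataclass
class OcclusionBand:
    """Horizontal band emulating shoulder overprojection."""

    row_start: int
    row_end: int
    dropout_prob: float = 1.0


@dataclass
class PhantomConfig:
    n_frames: int = 150  # ~10 s at 15 fps
    image_size: tuple[int, int] = (1024, 1024)  # (height, width)
    n_vertebrae: int = 8
    global_sweep_deg: Optional[float] = None  # defaults to the contribution sum
    segment_contributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRIBUTIONS)
    )
    bump_halfwidth: float = 0.2  # half-width of the rate bump, sweep fraction
    jitter_px: float = 0.0
    dropout_prob: float = 0.0
    occlusion: Optional[OcclusionBand] = None
    frame_rate_hz: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if not (2 <= self.n_vertebrae <= 8):
            raise ConfigError("n_vertebrae must be in [2, 8]")
        total = sum(e for e, _ in self.segment_contributions.values())
        if self.global_sweep_deg is None:
            self.global_sweep_deg = total
        elif abs(self.global_sweep_deg - total) > 1e-6:
            raise ConfigError(
                f"global_sweep_deg {self.global_sweep_deg} inconsistent with "
                f"contribution sum {total}"
            )
        for seg, (exc, peak) in self.segment_contributions.items():
            if exc < 0 or not (0.0 <= peak <= 1.0):
                raise ConfigError(f"bad contribution for {seg}: {(exc, peak)}")


@dataclass
class PhantomRecording:
    masks: LabelMaskSequence
    truth_theta: dict[str, np.ndarray]
    truth_segment: dict[str, dict]
    config: PhantomConfig

    def truth_rotation_traces(self) -> dict[str, RotationTrace]:
        out = {}
        n = self.config.n_frames
        for v, theta in self.truth_theta.items():
            dtheta = np.zeros(n)
            dtheta[1:] = np.diff(theta)
            out[v] = RotationTrace(
                vertebra=v,
                theta_deg=theta,
                dtheta_deg=dtheta,
                fit_overlap=np.ones(n),
            )
        return out

    def truth_segment_traces(self, sigma_frames: float = 3.0) -> dict[str, SegmentTrace]:
        out = {}
        for seg, d in self.truth_segment.items():
            rel = d["dtheta_rel"]
            smoothed = smooth_trace(rel, sigma_frames)
            cum = np.cumsum(smoothed)
            out[seg] = SegmentTrace(
                upper=seg.split("-")[0],
                lower=seg.split("-")[1],
                dtheta_rel_deg=rel,
                dtheta_rel_smoothed_deg=smoothed,
                sigma=sigma_frames,
                srom_deg=float(cum.max() - cum.min()),
            )
        return out


def _rate_profile(s: np.ndarray, peak: float, halfwidth: float) -> np.ndarray:
    """Raised-cosine bump on normalized time, zero outside |s - peak| > halfwidth."""
    z = (s - peak) / halfwidth
    out = np.where(np.abs(z) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * z)), 0.0)
    return out


def _segment_angle_curves(cfg: PhantomConfig) -> dict[str, np.ndarray]:
    """Per-segment cumulative angle phi(t), monotone from 0 to the excursion."""
    s = np.linspace(0.0, 1.0, cfg.n_frames)
    curves = {}
    for seg, (exc, peak) in cfg.segment_contributions.items():
        rate = _rate_profile(s, peak, cfg.bump_halfwidth)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]))])
        if cum[-1] > 0:
            cum = cum / cum[-1]
        curves[seg] = exc * cum
    return curves


def _geometry(cfg: PhantomConfig):
    h_img, w_img = cfg.image_size
    u = min(h_img, w_img) / 1024.0
    nv = cfg.n_vertebrae
    heights = [max(6.0, _REF_HEIGHTS[i] * u) for i in range(nv)]
    widths = [max(8.0, _REF_WIDTHS[i] * u) for i in range(nv)]
    gap = max(4.0, _REF_GAP * u)
    corner = max(2.0, _REF_CORNER * u)
    return heights, widths, gap, corner


def _poses(cfg: PhantomConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Forward kinematics: per-vertebra center (y, x) and absolute angle per frame."""
    h_img, w_img = cfg.image_size
    heights, widths, gap, _ = _geometry(cfg)
    nv = cfg.n_vertebrae
    names = VERTEBRA_NAMES[:nv]
    seg_curves = _segment_angle_curves(cfg)
    n = cfg.n_frames

    # absolute angle: sum of segment angles (motion + static posture) below
    theta = {names[nv - 1]: np.zeros(n)}
    for i in range(nv - 2, -1, -1):
        seg = segment_name(names[i], names[i + 1])
        phi = seg_curves.get(seg, np.zeros(n))
        posture = _POSTURE_DEG[i] if i < len(_POSTURE_DEG) else 0.0
        theta[names[i]] = theta[names[i + 1]] + phi + posture

    total_span = sum(heights) + gap * (nv - 1)
    base_y = (h_img + total_span) / 2.0 - heights[nv - 1] / 2.0
    centers = {names[nv - 1]: np.tile([base_y, w_img / 2.0], (n, 1)).astype(float)}
    for i in range(nv - 2, -1, -1):
        lower, upper = names[i + 1], names[i]
        c_lower = centers[lower]
        c_upper = np.empty_like(c_lower)
        for t in range(n):
            up_lower = _rotation_matrix(theta[lower][t]) @ np.array(
                [-(heights[i + 1] / 2.0 + gap / 2.0), 0.0]
            )
            joint = c_lower[t] + up_lower
            up_upper = _rotation_matrix(theta[upper][t]) @ np.array(
                [-(heights[i] / 2.0 + gap / 2.0), 0.0]
            )
            c_upper[t] = joint + up_upper
        centers[upper] = c_upper
    return {v: (centers[v], theta[v]) for v in names}


def _rounded_rect_sdf(y: np.ndarray, x: np.ndarray, hh: float, hw: float, rr: float):
    qy = np.abs(y) - (hh - rr)
    qx = np.abs(x) - (hw - rr)
    outside = np.hypot(np.maximum(qy, 0.0), np.maximum(qx, 0.0))
    inside = np.minimum(np.maximum(qy, qx), 0.0)
    return outside + inside - rr


def _vertebra_sdf(y: np.ndarray, x: np.ndarray, hh: float, hw: float, rr: float):
    """Vertebral body plus a posterior (spinous-process-like) protrusion.

    The protrusion breaks the body's near-elliptical symmetry, which real
    vertebrae also do; without it the rotation-overlap objective is poorly
    conditioned and angle recovery is unrealistically hard.
    """
    body = _rounded_rect_sdf(y, x, hh, hw, rr)
    proc = _rounded_rect_sdf(
        y - 0.15 * hh, x - (hw + 0.9 * hh), 0.38 * hh, 1.1 * hh, 0.6 * rr
    )
    return np.minimum(body, proc)


def _rasterize_vertebra(
    shape: tuple[int, int],
    center: np.ndarray,
    angle_deg: float,
    hh: float,
    hw: float,
    rr: float,
    noise_amp: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Optional[tuple[slice, slice, np.ndarray]]:
    h_img, w_img = shape
    radius = math.hypot(hh, hw + 2.0 * hh) + 3.0 * noise_amp + 3.0
    y0 = max(int(center[0] - radius), 0)
    y1 = min(int(center[0] + radius) + 2, h_img)
    x0 = max(int(center[1] - radius), 0)
    x1 = min(int(center[1] + radius) + 2, w_img)
    if y0 >= y1 or x0 >= x1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - center[0]
    dx = xx - center[1]
    rot = _rotation_matrix(-angle_deg)
    ly = rot[0, 0] * dy + rot[0, 1] * dx
    lx = rot[1, 0] * dy + rot[1, 1] * dx
    sdf = _vertebra_sdf(ly, lx, hh, hw, rr)
    if noise_amp > 0 and rng is not None:
        noise = rng.standard_normal(sdf.shape)
        noise = ndimage.gaussian_filter(noise, 3.0)
        sd = noise.std()
        if sd > 0:
            noise *= noise_amp / sd
        mask = sdf <= noise
    else:
        mask = sdf <= 0.0
    return slice(y0, y1), slice(x0, x1), mask


def generate(config: PhantomConfig) -> PhantomRecording:
    """Generate a phantom recording from a config; see module docstring."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    poses = _poses(cfg)
    names = list(poses)
    heights, widths, gap, corner = _geometry(cfg)
    h_img, w_img = cfg.image_size
    label_map = {i + 1: names[i] for i in range(len(names))}
    name_to_label = {v: k for k, v in label_map.items()}

    frames = []
    for t in range(cfg.n_frames):
        frame = np.zeros((h_img, w_img), dtype=np.uint8)
        clean_boxes = {}
        for i, v in enumerate(names):
            center, theta = poses[v]
            res = _rasterize_vertebra(
                (h_img, w_img), center[t], theta[t],
                heights[i] / 2.0, widths[i] / 2.0, corner,
            )
            if res is None:
                raise DataError(f"{v} left the image at frame {t}; config infeasible")
            clean_boxes[v] = res
        # adjacent clean polygons must not overlap
        for i in range(len(names) - 1):
            sy1, sx1, m1 = clean_boxes[names[i]]
            sy2, sx2, m2 = clean_boxes[names[i + 1]]
            oy = (max(sy1.start, sy2.start), min(sy1.stop, sy2.stop))
            ox = (max(sx1.start, sx2.start), min(sx1.stop, sx2.stop))
            if oy[0] < oy[1] and ox[0] < ox[1]:
                a = m1[oy[0] - sy1.start : oy[1] - sy1.start,
                       ox[0] - sx1.start : ox[1] - sx1.start]
                b = m2[oy[0] - sy2.start : oy[1] - sy2.start,
                       ox[0] - sx2.start : ox[1] - sx2.start]
                if np.any(a & b):
                    raise DataError(
                        f"vertebrae {names[i]}/{names[i + 1]} overlap at frame {t}; "
                        "config infeasible"
                    )
        for i, v in enumerate(names):
            if cfg.jitter_px > 0:
                center, theta = poses[v]
                res = _rasterize_vertebra(
                    (h_img, w_img), center[t], theta[t],
                    heights[i] / 2.0, widths[i] / 2.0, corner,
                    noise_amp=cfg.jitter_px, rng=rng,
                )
            else:
                res = clean_boxes[v]
            sy, sx, mask = res
            region = frame[sy, sx]
            paint = mask & (region == 0)
            region[paint] = name_to_label[v]
        if cfg.dropout_prob > 0:
            for v in names:
                if rng.random() < cfg.dropout_prob:
                    frame[frame == name_to_label[v]] = 0
        frames.append(frame)

    meta = RecordingMeta(
        recording_id=f"phantom-seed{cfg.seed}",
        frame_rate_hz=cfg.frame_rate_hz,
        width_px=w_img,
        height_px=h_img,
    )
    masks = LabelMaskSequence(meta=meta, frames=frames, label_map=label_map)
    if cfg.occlusion is not None:
        _apply_occlusion(masks, cfg.occlusion, rng)

    truth_theta = {v: poses[v][1].copy() for v in names}
    truth_segment = {}
    for i in range(len(names) - 1):
        seg = segment_name(names[i], names[i + 1])
        if seg not in cfg.segment_contributions:
            continue
        dth_u = np.zeros(cfg.n_frames)
        dth_u[1:] = np.diff(truth_theta[names[i]])
        dth_l = np.zeros(cfg.n_frames)
        dth_l[1:] = np.diff(truth_theta[names[i + 1]])
        rel = dth_u - dth_l
        cum = np.cumsum(rel)
        truth_segment[seg] = {
            "dtheta_rel": rel,
            "srom": float(cum.max() - cum.min()),
            "programmed_excursion": cfg.segment_contributions[seg][0],
            "programmed_peak": cfg.segment_contributions[seg][1],
        }
    return PhantomRecording(
        masks=masks, truth_theta=truth_theta, truth_segment=truth_segment, config=cfg
    )


def _apply_occlusion(
    masks: LabelMaskSequence, band: OcclusionBand, rng: np.random.Generator
) -> None:
    for frame in masks.frames:
        rows = frame[band.row_start : band.row_end]
        for label in np.unique(rows):
            if label == 0:
                continue
            if rng.random() < band.dropout_prob:
                rows[rows == label] = 0


def degrade(
    rec: PhantomRecording,
    jitter_px: float = 0.0,
    occlusion: Optional[OcclusionBand] = None,
    seed: int = 0,
) -> PhantomRecording:
    """Apply additional degradation to the masks; truth fields are untouched.

    Boundary jitter perturbs each label's signed distance field with smooth
    noise of the given amplitude; the occlusion band drops covered labels
    probabilistically.
    """
    rng = np.random.default_rng(seed)
    new_frames = []
    for frame in rec.masks.frames:
        out = frame.copy()
        if jitter_px > 0:
            out = np.zeros_like(frame)
            for label in np.unique(frame):
                if label == 0:
                    continue
                m = frame == label
                inside = ndimage.distance_transform_edt(m)
                outside = ndimage.distance_transform_edt(~m)
                sdf = outside - inside  # negative inside
                ys, xs = np.nonzero(m)
                pad = int(3 * jitter_px) + 3
                y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad, m.shape[0])
                x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad, m.shape[1])
                noise = rng.standard_normal((y1 - y0, x1 - x0))
                noise = ndimage.gaussian_filter(noise, 3.0)
                sd = noise.std()
                if sd > 0:
                    noise *= jitter_px / sd
                sub = sdf[y0:y1, x0:x1] <= noise
                region = out[y0:y1, x0:x1]
                paint = sub & (region == 0)
                region[paint] = label
        new_frames.append(out)
    meta = copy.deepcopy(rec.masks.meta)
    masks = LabelMaskSequence(
        meta=meta, frames=new_frames, label_map=dict(rec.masks.label_map)
    )
    if occlusion is not None:
        _apply_occlusion(masks, occlusion, rng)
    new_cfg = replace(rec.config, jitter_px=max(rec.config.jitter_px, jitter_px))
    return PhantomRecording(
        masks=masks,
        truth_theta={k: v.copy() for k, v in rec.truth_theta.items()},
        truth_segment=copy.deepcopy(rec.truth_segment),
        config=new_cfg,
    )


def render_intensity(
    rec: PhantomRecording, noise_sd: float = 8.0, seed: int = 0
) -> list[np.ndarray]:
    """Flat-shaded 8-bit intensity frames (bone bright, background dark)."""
    rng = np.random.default_rng(seed)
    out = []
    for frame in rec.masks.frames:
        img = np.where(frame > 0, 180.0, 30.0)
        img += rng.normal(0.0, noise_sd, size=img.shape)
        out.append(np.clip(img, 0, 255).astype(np.uint8))
    return out
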