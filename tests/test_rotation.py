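import numpy as np
import pytest

from cervtrack.errors import ConfigError, DataError, DimensionError
from cervtrack.phantom import _rasterize_vertebra
from cervtrack.rotation import (
    FitConfig,
    fit_angle,
    relative_rotation,
    segment_traces,
    track_vertebra,
)
from cervtrack.datamodel import RotationTrace


def _shape_at(angle, center=(100.0, 120.0), size=(220, 260), hh=14.0, hw=26.0):
    _, _, mask = _rasterize_vertebra(
        size, np.array(center), angle, hh, hw, 3.0
    )
    full = np.zeros(size, dtype=bool)
    # _rasterize_vertebra returns slices + mask on a bounding box
    sy, sx, m = _rasterize_vertebra(size, np.array(center), angle, hh, hw, 3.0)
    full[sy, sx] = m
    return full


class TestFitConfig:
    def test_bad_step(self):
        with pytest.raises(ConfigError):
            FitConfig(coarse_step_deg=0)

    def test_bad_tol(self):
        with pytest.raises(ConfigError):
            FitConfig(refine_tol_deg=-1)

    def test_bad_criterion(self):
        with pytest.raises(ConfigError):
            FitConfig(overlap_criterion="nope")


class TestFitAngle:
    def test_identity_pose(self):
        tpl = _shape_at(0.0)
        res = fit_angle(tpl, tpl, 0.0)
        assert abs(res.angle_deg) <= 0.25
        assert res.overlap >= 0.99

    @pytest.mark.parametrize("angle", [-30.0, -7.0, 0.0, 7.0, 30.0])
    def test_known_rotation_recovered(self, angle):
        # oracle: the rasterization's known rotation
        tpl = _shape_at(0.0)
        mask = _shape_at(angle)
        res = fit_angle(tpl, mask, 0.0)
        assert res.angle_deg == pytest.approx(angle, abs=0.5)

    def test_window_constrains_result(self):
        tpl = _shape_at(0.0)
        mask = _shape_at(100.0)
        res = fit_angle(tpl, mask, 0.0, FitConfig(overlap_floor=0.95))
        assert -90.0 <= res.angle_deg <= 90.0
        assert res.overlap < 0.95
        assert res.low_confidence

    def test_empty_mask_missing(self):
        tpl = _shape_at(0.0)
        res = fit_angle(tpl, np.zeros((50, 50), dtype=bool), 0.0)
        assert res.missing

    def test_translation_invariance(self):
        tpl = _shape_at(0.0)
        a = _shape_at(12.0, center=(80.0, 90.0))
        b = _shape_at(12.0, center=(130.0, 150.0))
        ra = fit_angle(tpl, a, 0.0)
        rb = fit_angle(tpl, b, 0.0)
        assert ra.angle_deg == pytest.approx(rb.angle_deg, abs=0.2)
        assert ra.overlap == pytest.approx(rb.overlap, abs=0.02)

    def test_intersection_criterion(self):
        tpl = _shape_at(0.0)
        mask = _shape_at(5.0)
        res = fit_angle(tpl, mask, 0.0, FitConfig(overlap_criterion="intersection"))
        assert res.angle_deg == pytest.approx(5.0, abs=0.6)


class TestTrackVertebra:
    def test_linear_sweep_recovery(self):
        # native-resolution phantom: angle bias grows at coarser scales
        from cervtrack.mean_shape import build_mean_shape
        from cervtrack.phantom import PhantomConfig, generate

        rec = generate(PhantomConfig(n_frames=60, image_size=(1024, 1024), seed=7))
        shape = build_mean_shape(rec.masks, "C5")
        trace = track_vertebra(rec.masks, shape)
        truth = rec.truth_theta["C5"]
        resid = trace.theta_deg - truth
        resid -= resid.mean()  # constant template-orientation offset
        assert np.abs(resid).max() <= 0.5

    def test_static_vertebra_zero_deltas(self, mid_phantom):
        # C7 is the static reference of the chain
        from cervtrack.mean_shape import build_mean_shape

        rec = mid_phantom
        shape = build_mean_shape(rec.masks, "C7")
        trace = track_vertebra(rec.masks, shape)
        assert np.abs(trace.dtheta_deg).max() <= 0.1

    def test_telescoping_sum(self, mid_phantom):
        from cervtrack.mean_shape import build_mean_shape

        rec = mid_phantom
        shape = build_mean_shape(rec.masks, "C4")
        trace = track_vertebra(rec.masks, shape)
        assert trace.dtheta_deg[0] == 0.0
        assert trace.dtheta_deg[1:].sum() == pytest.approx(
            trace.theta_deg[-1] - trace.theta_deg[0], abs=1e-9
        )

    def test_missing_frames_recorded(self, small_phantom):
        from cervtrack.mean_shape import build_mean_shape

        rec = small_phantom
        shape = build_mean_shape(rec.masks, "C3")
        frames = [f.copy() for f in rec.masks.frames]
        label = rec.masks.label_of("C3")
        frames[5][frames[5] == label] = 0
        from conftest import make_sequence

        seq = make_sequence(frames, label_map=rec.masks.label_map)
        trace = track_vertebra(seq, shape)
        assert 5 in trace.missing_frames
        assert np.isnan(trace.theta_deg[5])
        assert np.isnan(trace.dtheta_deg[5])
        assert np.isnan(trace.dtheta_deg[6])

    def test_all_empty_errors(self, small_phantom):
        from cervtrack.mean_shape import build_mean_shape
        from conftest import make_sequence

        rec = small_phantom
        shape = build_mean_shape(rec.masks, "C3")
        frames = [np.zeros_like(f) for f in rec.masks.frames]
        seq = make_sequence(frames, label_map=rec.masks.label_map)
        with pytest.raises(DataError):
            track_vertebra(seq, shape)

    def test_no_jump_exceeds_window(self, mid_phantom):
        from cervtrack.mean_shape import build_mean_shape

        rec = mid_phantom
        shape = build_mean_shape(rec.masks, "C2")
        trace = track_vertebra(rec.masks, shape)
        deltas = np.diff(trace.theta_deg)
        assert np.nanmax(np.abs(deltas)) <= 90.0


def _rt(name, dtheta):
    dtheta = np.asarray(dtheta, dtype=float)
    theta = np.cumsum(np.nan_to_num(dtheta))
    return RotationTrace(name, theta, dtheta, np.ones(len(dtheta)))


class TestRelativeRotation:
    def test_self_difference_zero(self):
        tr = _rt("C4", [0, 1, 2, 1])
        seg = relative_rotation(tr, _rt("C5", [0, 1, 2, 1]))
        np.testing.assert_allclose(seg.dtheta_rel_deg, 0.0)

    def test_arithmetic(self):
        up = _rt("C4", [0, 1, 1, 0])
        lo = _rt("C5", [0, 0.5, 0.5, 0])
        seg = relative_rotation(up, lo)
        np.testing.assert_allclose(seg.dtheta_rel_deg, [0, 0.5, 0.5, 0])

    def test_missing_propagates(self):
        up = _rt("C4", [0, 1, np.nan, 0])
        lo = _rt("C5", [0, 0.5, 0.5, 0])
        seg = relative_rotation(up, lo)
        assert np.isnan(seg.dtheta_rel_deg[2])

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            relative_rotation(_rt("C4", [0, 1]), _rt("C5", [0, 1, 2]))

    def test_cumulative_matches_phantom(self, mid_phantom):
        rec = mid_phantom
        truth_traces = rec.truth_rotation_traces()
        seg = relative_rotation(truth_traces["C5"], truth_traces["C6"])
        cum = np.cumsum(seg.dtheta_rel_deg)
        programmed = rec.truth_segment["C5-C6"]["dtheta_rel"]
        np.testing.assert_allclose(cum, np.cumsum(programmed), atol=1e-9)

    def test_segment_traces_builder(self):
        traces = {n: _rt(n, [0, 1, 2]) for n in ("C4", "C5", "C6")}
        segs = segment_traces(traces)
        assert set(segs) == {"C4-C5", "C5-C6"}
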