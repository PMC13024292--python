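import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from cervtrack.errors import DimensionError
from cervtrack.seg_metrics import (
    boundary_pixels,
    dsc,
    evaluate_sequence,
    hd95,
    iou,
    metrics_table,
)

from conftest import make_sequence


def brute_force_hd95(a, b):
    """Exhaustive all-pairs boundary-distance oracle."""
    pa = np.argwhere(boundary_pixels(a))
    pb = np.argwhere(boundary_pixels(b))
    d = cdist(pa, pb)
    return max(
        np.percentile(d.min(axis=1), 95),
        np.percentile(d.min(axis=0), 95),
    )


class TestDice:
    def test_identical_masks(self):
        a = np.zeros((10, 10), dtype=bool)
        a[2:6, 2:6] = True
        assert dsc(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[0:2, 0:2] = True
        b[5:7, 5:7] = True
        assert dsc(a, b) == 0.0

    def test_constructed_counts(self, square_pair):
        a, b = square_pair
        # oracle: direct pixel counting, 2*50/(100+100)
        assert dsc(a, b) == pytest.approx(0.5)

    def test_both_empty_nan(self):
        a = np.zeros((5, 5), dtype=bool)
        with pytest.warns(UserWarning):
            assert np.isnan(dsc(a, a))

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            dsc(np.ones((3, 3), bool), np.ones((4, 4), bool))


class TestIoU:
    def test_identical(self):
        a = np.ones((4, 4), dtype=bool)
        assert iou(a, a) == 1.0

    def test_constructed_counts(self, square_pair):
        a, b = square_pair
        assert iou(a, b) == pytest.approx(1.0 / 3.0)

    def test_iou_le_dsc_random(self, rng):
        for _ in range(50):
            a = rng.random((16, 16)) > 0.5
            b = rng.random((16, 16)) > 0.5
            if not (a.any() or b.any()):
                continue
            assert iou(a, b) <= dsc(a, b) + 1e-15

    def test_dice_iou_identity_random(self, rng):
        # dsc = 2*iou/(1+iou), algebraic identity, machine precision
        for _ in range(100):
            a = rng.random((32, 32)) > 0.6
            b = rng.random((32, 32)) > 0.6
            if not (a.any() or b.any()):
                continue
            j = iou(a, b)
            assert dsc(a, b) == pytest.approx(2 * j / (1 + j), abs=1e-12)


class TestHD95:
    def test_identical_zero(self):
        a = np.zeros((20, 20), dtype=bool)
        a[5:15, 5:15] = True
        assert hd95(a, a) == 0.0

    def test_offset_squares_matches_bruteforce(self):
        a = np.zeros((40, 40), dtype=bool)
        b = np.zeros((40, 40), dtype=bool)
        a[10:30, 5:25] = True
        b[10:30, 10:30] = True  # 5 px horizontal offset
        v = hd95(a, b)
        assert v == pytest.approx(brute_force_hd95(a, b), abs=1e-9)
        assert v == pytest.approx(5.0, abs=0.5)

    def test_spacing_linearity(self):
        a = np.zeros((30, 30), dtype=bool)
        b = np.zeros((30, 30), dtype=bool)
        a[5:15, 5:15] = True
        b[8:18, 7:17] = True
        assert hd95(a, b, spacing=0.2) == pytest.approx(0.2 * hd95(a, b), rel=1e-12)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = ndimage.binary_dilation(rng.random((24, 24)) > 0.8)
            b = ndimage.binary_dilation(rng.random((24, 24)) > 0.8)
            if not (a.any() and b.any()):
                continue
            assert hd95(a, b) == pytest.approx(hd95(b, a), abs=1e-12)

    def test_translation_monotonicity(self):
        base = np.zeros((60, 60), dtype=bool)
        base[20:40, 10:30] = True
        prev = -1.0
        for d in range(11):
            shifted = np.roll(base, d, axis=1)
            v = hd95(base, shifted)
            assert v >= prev - 1e-12
            prev = v

    def test_empty_mask_nan(self):
        a = np.zeros((5, 5), dtype=bool)
        b = np.ones((5, 5), dtype=bool)
        with pytest.warns(UserWarning):
            assert np.isnan(hd95(a, b))

    def test_bruteforce_equivalence_random(self, rng):
        # distance-transform HD95 == exhaustive all-pairs HD95
        checked = 0
        while checked < 30:
            a = ndimage.binary_closing(rng.random((32, 32)) > 0.7)
            b = ndimage.binary_closing(rng.random((32, 32)) > 0.7)
            if not (a.any() and b.any()):
                continue
            assert hd95(a, b) == pytest.approx(brute_force_hd95(a, b), abs=1e-9)
            checked += 1


class TestEvaluateSequence:
    def _seqs(self):
        frames = []
        for _ in range(3):
            f = np.zeros((64, 64), dtype=np.uint8)
            f[10:30, 10:30] = 5  # C4
            f[35:55, 10:30] = 6  # C5
            frames.append(f)
        gt = make_sequence(frames)
        pred = make_sequence([f.copy() for f in frames])
        return pred, gt

    def test_perfect_prediction(self):
        pred, gt = self._seqs()
        results = evaluate_sequence(pred, gt)
        for r in results:
            assert r.mean_sd["dsc"][0] == 1.0
            assert r.mean_sd["iou"][0] == 1.0
            assert r.mean_sd["hd95"][0] == 0.0
            assert r.flags["dsc_ok"] and r.flags["iou_ok"]

    def test_dilated_prediction_matches_pixel_count_oracle(self):
        pred, gt = self._seqs()
        for f in pred.frames:
            m = ndimage.binary_dilation(f == 5)
            f[m] = 5
        results = {r.vertebra: r for r in evaluate_sequence(pred, gt)}
        gm = gt.frames[0] == 5
        pm = pred.frames[0] == 5
        expected = 2 * (gm & pm).sum() / (gm.sum() + pm.sum())
        assert results["C4"].per_frame["dsc"].iloc[0] == pytest.approx(expected)

    def test_empty_frame_excluded(self):
        pred, gt = self._seqs()
        pred.frames[1][pred.frames[1] == 5] = 0
        results = {r.vertebra: r for r in evaluate_sequence(pred, gt)}
        assert results["C4"].excluded_frames == [1]
        assert len(results["C4"].per_frame) == 2

    def test_hd95_unit_flags(self):
        pred, gt = self._seqs()
        results = evaluate_sequence(pred, gt)
        assert all(r.hd95_unit == "px" for r in results)
        assert not any(r.flags["hd95_ok"] for r in results)  # px => not ok-able
        gt.meta.pixel_spacing_mm = 0.2
        results = evaluate_sequence(pred, gt)
        assert all(r.hd95_unit == "mm" for r in results)
        assert all(r.flags["hd95_ok"] for r in results)

    def test_frame_count_mismatch(self):
        pred, gt = self._seqs()
        short = make_sequence(gt.frames[:2])
        with pytest.raises(DimensionError):
            evaluate_sequence(pred, short)

    def test_metrics_table_shape(self):
        pred, gt = self._seqs()
        table = metrics_table(evaluate_sequence(pred, gt))
        assert set(table["vertebra"]) == {"C4", "C5"}
        assert {"dsc_mean", "iou_sd", "hd95_mean"} <= set(table.columns)
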