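import numpy as np
import pytest

from cervtrack.datamodel import SegmentTrace
from cervtrack.errors import DataError, InsufficientDataError
from cervtrack.reliability import (
    ICCResult,
    icc_3_1,
    metric_icc_correlation,
    segment_icc_table,
)
from cervtrack.seg_metrics import evaluate_sequence
from cervtrack.smoothing import smooth_trace


def brute_force_icc31(x, y):
    """Hand-rolled two-way ANOVA sum-of-squares oracle for ICC(3,1)."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


def _trace(name, rel, sigma=3.0):
    up, lo = name.split("-")
    sm = smooth_trace(rel, sigma)
    cum = np.cumsum(np.nan_to_num(sm))
    return SegmentTrace(
        upper=up, lower=lo, dtheta_rel_deg=np.asarray(rel, float),
        dtheta_rel_smoothed_deg=sm, sigma=sigma,
        srom_deg=float(cum.max() - cum.min()),
    )


class TestICC:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        res = icc_3_1(x, x)
        assert res.icc == 1.0
        assert res.ci_high == 1.0

    def test_constant_shift_is_one(self):
        # consistency model ignores additive rater offsets
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        res = icc_3_1(x, x + 5.0)
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_small_table_matches_anova_oracle(self):
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([1, 3, 2, 4, 6, 5], dtype=float)
        assert icc_3_1(x, y).icc == pytest.approx(brute_force_icc31(x, y), abs=1e-9)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 21))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if np.var(np.column_stack([x, y]).mean(axis=1)) == 0:
                continue
            assert icc_3_1(x, y).icc == pytest.approx(
                brute_force_icc31(x, y), abs=1e-9
            )

    def test_affine_invariance(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.3, size=12)
        base = icc_3_1(x, y).icc
        assert icc_3_1(3.0 * x - 2.0, 3.0 * y - 2.0).icc == pytest.approx(base)
        assert icc_3_1(x + 4.0, y - 1.0).icc == pytest.approx(base)

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        res = icc_3_1(x, y)
        assert res.ci_low <= res.icc <= res.ci_high
        assert res.icc <= 1.0

    def test_nan_frames_dropped(self):
        x = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        assert icc_3_1(x, y).n_frames == 3

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            icc_3_1(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_zero_variance_degenerate(self):
        with pytest.warns(UserWarning):
            res = icc_3_1(np.zeros(5), np.zeros(5))
        assert np.isnan(res.icc)

    def test_flags(self):
        r = ICCResult("s", 0.7, 0.1, 0.9, 10)
        assert r.acceptable and not r.excellent


class TestSegmentICCTable:
    def _batch(self, rng, noise=0.0, n_rec=5):
        pred, gt = {}, {}
        t = np.linspace(0, 1, 40)
        signal = np.sin(2 * np.pi * t) * 0.5
        for i in range(n_rec):
            rec = f"r{i}"
            gt[rec] = {"C4-C5": _trace("C4-C5", signal)}
            noisy = signal + rng.normal(scale=noise, size=signal.size)
            pred[rec] = {"C4-C5": _trace("C4-C5", noisy)}
        return pred, gt

    def test_perfect_agreement(self, rng):
        pred, gt = self._batch(rng, noise=0.0)
        report = segment_icc_table(pred, gt)
        assert (report.per_segment["icc_mean"] == 1.0).all()
        assert (report.per_segment["n"] == 5).all()

    def test_noise_ordering(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        low = segment_icc_table(*self._batch(rng1, noise=0.05))
        high = segment_icc_table(*self._batch(rng2, noise=0.4))
        assert (
            low.per_segment["icc_mean"].iloc[0]
            > high.per_segment["icc_mean"].iloc[0]
        )

    def test_low_srom_filter_bookkeeping(self, rng):
        t = np.linspace(0, 1, 40)
        big = np.gradient(np.sin(np.pi * t)) * 20  # large excursion
        small = np.gradient(np.sin(np.pi * t)) * 1  # sROM < 4
        pred = {"r0": {"C4-C5": _trace("C4-C5", big), "C6-C7": _trace("C6-C7", small)}}
        gt = {"r0": {"C4-C5": _trace("C4-C5", big), "C6-C7": _trace("C6-C7", small)}}
        report = segment_icc_table(pred, gt, filters={"low_srom"})
        assert set(report.per_segment["segment"]) == {"C4-C5"}
        assert [e[1] for e in report.excluded] == ["C6-C7"]

    def test_low_quality_filter(self, rng):
        pred, gt = self._batch(rng, n_rec=3)
        quality = {"r1": {"C4-C5": "low"}}
        report = segment_icc_table(
            pred, gt, filters={"low_quality"}, quality=quality
        )
        assert report.per_segment["n"].iloc[0] == 2

    def test_unmatched_keys_error(self, rng):
        pred, gt = self._batch(rng)
        del gt["r0"]
        with pytest.raises(DataError):
            segment_icc_table(pred, gt)


class TestMetricICCCorrelation:
    def _metrics_for(self, seq_pair):
        pred, gt = seq_pair
        return evaluate_sequence(pred, gt)

    def test_sign_forced_by_construction(self, rng):
        from scipy import ndimage as ndi

        from conftest import make_sequence

        icc_by_rec, metrics_by_rec = {}, {}
        t = np.linspace(0, 1, 30)
        signal = np.sin(2 * np.pi * t)
        for i, n_dilate in enumerate([0, 1, 2, 3, 4]):
            rec = f"r{i}"
            frames_gt, frames_pred = [], []
            for _ in range(3):
                f = np.zeros((64, 64), dtype=np.uint8)
                f[20:40, 20:40] = 5
                frames_gt.append(f)
                g = f.copy()
                if n_dilate:
                    m = ndi.binary_dilation(f == 5, iterations=n_dilate)
                    g[m] = 5
                frames_pred.append(g)
            metrics_by_rec[rec] = evaluate_sequence(
                make_sequence(frames_pred), make_sequence(frames_gt)
            )
            noisy = signal + rng.normal(scale=0.05 * (1 + n_dilate), size=signal.size)
            icc_by_rec[rec] = icc_3_1(noisy, signal).icc
        table = metric_icc_correlation(icc_by_rec, metrics_by_rec)
        r_dsc_mean = table[
            (table["metric"] == "dsc") & (table["statistic"] == "mean")
        ]["r"].iloc[0]
        assert r_dsc_mean > 0

    def test_constant_metrics_give_nan(self, rng):
        from conftest import make_sequence

        frames = []
        for _ in range(3):
            f = np.zeros((32, 32), dtype=np.uint8)
            f[5:20, 5:20] = 5
            frames.append(f)
        res = evaluate_sequence(make_sequence(frames), make_sequence(frames))
        icc_by_rec = {f"r{i}": 0.5 + 0.1 * i for i in range(3)}
        metrics_by_rec = {f"r{i}": res for i in range(3)}
        with pytest.warns(UserWarning):
            table = metric_icc_correlation(icc_by_rec, metrics_by_rec)
        assert table["r"].isna().all()

    def test_requires_three_recordings(self):
        with pytest.raises(InsufficientDataError):
            metric_icc_correlation({"a": 1.0}, {"a": []})

    def test_pearson_properties(self, rng):
        x = rng.normal(size=10)
        y = x + rng.normal(size=10)
        from scipy import stats

        r1 = stats.pearsonr(x, y)[0]
        r2 = stats.pearsonr(y, x)[0]
        assert r1 == pytest.approx(r2)
        assert abs(r1) <= 1
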