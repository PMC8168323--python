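"""Cleaning pipeline: sorting, scale detection, fencing, monotonicity, partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmipd.exceptions import (
    EmptyIntervalWarning,
    InvalidInputError,
    InvalidRiskTableError,
    MissingInputError,
)
from kmipd.preprocess import (
    CurvePoints,
    CurvePreprocessor,
    RiskTable,
    force_monotone,
    normalize_and_sort,
    partition_intervals,
    preprocess,
    step_control,
    tukey_outlier_filter,
)

from conftest import make_points


class TestNormalizeAndSort:
    def test_sorts_detects_percent_and_anchors(self):
        pts, scale = normalize_and_sort(CurvePoints([5, 2], [80, 95]))
        assert scale == 100.0
        np.testing.assert_allclose(pts.times, [0, 2, 5])
        np.testing.assert_allclose(pts.surv, [1.0, 0.95, 0.80])

    def test_clean_fraction_input_is_identity(self):
        pts, scale = normalize_and_sort(CurvePoints([0, 3], [1.0, 0.7]))
        assert scale == 1.0
        np.testing.assert_allclose(pts.times, [0, 3])
        np.testing.assert_allclose(pts.surv, [1.0, 0.7])

    def test_stable_sort_keeps_drop_order_at_tied_times(self):
        pts, _ = normalize_and_sort(CurvePoints([0, 4, 4], [1.0, 0.8, 0.6]))
        np.testing.assert_allclose(pts.surv, [1.0, 0.8, 0.6])

    @pytest.mark.parametrize(
        "times,surv",
        [([1], [0.5]), ([1, 2], [0.5, -0.1]), ([-1, 2], [1.0, 0.5]),
         ([1, np.nan], [1.0, 0.5])],
    )
    def test_invalid_inputs_rejected(self, times, surv):
        with pytest.raises(InvalidInputError):
            normalize_and_sort(CurvePoints(times, surv))


class TestTukeyFence:
    def test_single_level_shift_outlier_removed(self):
        # 20 increments of -0.01 and one of +0.30: quartiles are both -0.01,
        # the fence collapses to [-0.01, 0], and only the jump is outside
        surv = np.round(
            list(np.linspace(1.0, 0.85, 16))
            + [1.15]
            + list(1.15 - 0.01 * np.arange(1, 6)),
            10,
        )
        inc = np.round(np.diff(surv), 10)
        assert np.sum(inc == -0.01) == 20 and inc.max() == 0.30
        pts = CurvePoints(np.arange(len(surv), dtype=float), surv)
        out, removed = tukey_outlier_filter(pts)
        assert list(removed) == [16]
        assert out.n == pts.n - 1

    def test_spike_above_removes_only_the_spike(self):
        surv = 1.0 - 0.01 * np.arange(20.0)
        surv[10] += 0.30  # one click far above the curve
        out, removed = tukey_outlier_filter(CurvePoints(np.arange(20.0), surv))
        assert list(removed) == [10]
        # the recovery point after the spike is kept
        assert 0.89 in np.round(out.surv, 10)

    def test_spike_below_removed_when_curve_recovers(self):
        surv = 1.0 - 0.01 * np.arange(20.0)
        surv[10] -= 0.30
        out, removed = tukey_outlier_filter(CurvePoints(np.arange(20.0), surv))
        assert list(removed) == [10]

    def test_clean_monotone_curve_unchanged(self):
        surv = np.array([1.0, 0.95, 0.9, 0.9, 0.55, 0.5, 0.5, 0.2])
        out, removed = tukey_outlier_filter(CurvePoints(np.arange(8.0), surv))
        assert removed.size == 0
        np.testing.assert_array_equal(out.surv, surv)

    def test_short_curves_pass_through(self):
        out, removed = tukey_outlier_filter(CurvePoints([0, 1, 2], [1.0, 2.0, 0.1]))
        assert out.n == 3 and removed.size == 0


class TestForceMonotoneAndStepControl:
    def test_running_minimum(self):
        out = force_monotone(CurvePoints([0, 1, 2, 3], [1.0, 0.8, 0.85, 0.7]))
        np.testing.assert_allclose(out.surv, [1.0, 0.8, 0.8, 0.7])

    def test_monotone_input_unchanged(self):
        s = np.array([1.0, 0.8, 0.8, 0.7])
        out = force_monotone(CurvePoints(np.arange(4.0), s))
        np.testing.assert_array_equal(out.surv, s)

    def test_vertical_run_reduced_to_two_points(self):
        out = step_control(CurvePoints([4, 4, 4], [0.8, 0.7, 0.6]))
        np.testing.assert_allclose(out.times, [4, 4])
        np.testing.assert_allclose(out.surv, [0.8, 0.6])

    def test_distinct_times_unchanged(self):
        out = step_control(CurvePoints([1, 2, 3], [1.0, 0.9, 0.8]))
        assert out.n == 3

    def test_subdivided_drop_collapses_keeping_extremes(self):
        # s=10 sub-points inside one vertical segment -> top and bottom only
        t = np.concatenate([[0.0], np.full(10, 5.0)])
        s = np.concatenate([[1.0], np.linspace(0.9, 0.5, 10)])
        out = step_control(CurvePoints(t, s))
        np.testing.assert_allclose(out.times, [0, 5, 5])
        np.testing.assert_allclose(out.surv, [1.0, 0.9, 0.5])
        # distinct times and per-time minima are preserved
        assert set(out.times) == set(t)
        assert out.surv[-1] == s.min()


class TestPartition:
    def test_two_interval_bookkeeping_matches_brute_force(self):
        t = np.arange(20.0)
        s = 1.0 - 0.01 * t
        risk = RiskTable([0.0, 10.0], [100, 60])
        prep = partition_intervals(CurvePoints(t, s), risk=risk)
        # brute-force scan: which points belong to each half-open window
        expect0 = [k for k in range(20) if 0 <= t[k] < 10]
        expect1 = [k for k in range(20) if t[k] >= 10]
        assert list(range(prep.lower[0], prep.upper[0] + 1)) == expect0
        assert list(range(prep.lower[1], prep.upper[1] + 1)) == expect1

    def test_no_risk_table_single_interval(self):
        prep = partition_intervals(
            CurvePoints(np.arange(5.0), np.linspace(1, 0.6, 5)), total_n=100
        )
        assert prep.n_intervals == 1
        assert prep.lower[0] == 0 and prep.upper[0] == 4
        assert prep.total_n == 100 and not prep.has_risk_table

    def test_empty_interval_warns_and_keeps_contiguity(self):
        t = np.array([0.0, 2.0, 25.0])
        s = np.array([1.0, 0.8, 0.6])
        with pytest.warns(EmptyIntervalWarning):
            prep = partition_intervals(
                CurvePoints(t, s), risk=RiskTable([0, 10, 20], [50, 30, 20])
            )
        assert prep.upper[1] == prep.lower[1] - 1  # empty middle interval
        assert prep.upper[0] + 1 == prep.lower[1]
        assert prep.upper[1] + 1 == prep.lower[2]

    def test_missing_total_n_and_bad_risk_tables_rejected(self):
        pts = CurvePoints([0.0, 1.0], [1.0, 0.5])
        with pytest.raises(MissingInputError):
            partition_intervals(pts)
        with pytest.raises(InvalidRiskTableError):
            RiskTable([0, 0], [10, 5])
        with pytest.raises(InvalidRiskTableError):
            RiskTable([0, 5], [10, 15])
        with pytest.raises(InvalidRiskTableError):
            RiskTable([0, 5, 10], [10, 5])


class TestPipeline:
    def test_outlier_and_monotonicity_both_repaired(self):
        t = np.arange(30.0)
        s = 1.0 - 0.01 * t
        s[7] += 0.25       # gross blunder (fenced out)
        s[15] += 0.004     # small wobble (flattened, not deleted)
        prep = preprocess(make_points(t, s), total_n=50)
        assert prep.points.n == 30 - 1
        assert np.all(np.diff(prep.points.surv) <= 0)

    def test_survival_bounds_and_monotone_after_preprocess(self, treat_arm):
        from kmipd.simulate import digitization_noise

        noisy = digitization_noise(treat_arm.points, sd_s=0.01, seed=4)
        prep = preprocess(noisy, risk=treat_arm.risk)
        s = prep.points.surv
        assert np.all((0 <= s) & (s <= 1))
        assert np.all(np.diff(s) <= 0)

    def test_partition_indices_disjoint_cover(self, treat_prep):
        covered = []
        for lo, up in zip(treat_prep.lower, treat_prep.upper):
            covered.extend(range(lo, up + 1))
        assert covered == list(range(treat_prep.points.n))

    def test_sklearn_transformer_surface(self, treat_arm):
        tr = CurvePreprocessor(
            trisk=treat_arm.risk.trisk, nrisk=treat_arm.risk.nrisk
        )
        X = treat_arm.points.to_array()
        out = tr.fit_transform(X)
        assert out.shape[1] == 2
        assert tr.n_intervals_ == len(treat_arm.risk.trisk)
        params = tr.get_params()
        assert params["fence_k"] == 3.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10**6),
        n=st.integers(5, 60),
        pct=st.booleans(),
    )
    def test_preprocess_idempotent_and_in_bounds(self, seed, n, pct):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 40, n))
        s = np.clip(np.linspace(1, 0.2, n) + rng.normal(0, 0.03, n), 0, 1.1)
        raw = make_points(t, (s * 100) if pct else s)
        p1 = preprocess(raw, total_n=50)
        assert np.all(np.diff(p1.points.surv) <= 0)
        assert np.all((0 <= p1.points.surv) & (p1.points.surv <= 1))
        p2 = preprocess(p1.points.to_array(), total_n=50)
        np.testing.assert_array_equal(p1.points.times, p2.points.times)
        np.testing.assert_array_equal(p1.points.surv, p2.points.surv)
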