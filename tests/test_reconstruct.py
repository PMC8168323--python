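"""Iterative event/censor estimation: formulas, box constraints, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmipd.exceptions import DegenerateCurveError
from kmipd.km import km_fit, surv_at
from kmipd.preprocess import CurvePoints, RiskTable, partition_intervals, preprocess
from kmipd.reconstruct import (
    KaplanMeierReconstructor,
    censor_times_for_interval,
    fit_interval,
    init_censor_interval,
    last_interval_censor_init,
    reconstruct_ipd,
    round_half,
    sweep_interval,
)
from kmipd.simulate import SimConfig, simulate_trial

from conftest import make_points


class TestInitCensor:
    def test_formula_and_clamping(self):
        assert init_censor_interval(100, 1.0, 0.8, 70) == 10
        assert init_censor_interval(100, 1.0, 0.7, 70) == 0
        # formula would give -10; the admissible box clamps at 0
        assert init_censor_interval(100, 1.0, 0.6, 70) == 0

    def test_zero_survival_start_is_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            init_censor_interval(100, 0.0, 0.0, 70)

    def test_rounding_half_away_from_zero(self):
        assert round_half(2.5) == 3
        assert round_half(-2.5) == -3
        assert round_half(2.4) == 2


class TestCensorTimes:
    @pytest.mark.parametrize(
        "t_lo,t_hi,n,expect",
        [
            (10, 20, 3, [12.5, 15.0, 17.5]),
            (0, 10, 4, [2.0, 4.0, 6.0, 8.0]),
            (0, 10, 0, []),
        ],
    )
    def test_even_spacing(self, t_lo, t_hi, n, expect):
        np.testing.assert_allclose(censor_times_for_interval(t_lo, t_hi, n), expect)


def _prep_single_interval(times, surv, n0, t_next=None, n_next=None):
    """Small curve with one (or two) reporting intervals, bypassing cleaning."""
    pts = CurvePoints(np.asarray(times, float), np.asarray(surv, float))
    if t_next is None:
        return partition_intervals(pts, total_n=n0)
    risk = RiskTable([times[0], t_next], [n0, n_next])
    return partition_intervals(pts, risk=risk)


class TestSweep:
    def test_event_count_from_product_limit_ratio(self):
        # S drops from 1.0 to 0.9 with 50 at risk -> d = round(5.0) = 5
        prep = _prep_single_interval([0, 4, 4, 8], [1.0, 1.0, 0.9, 0.9], 50)
        frag = sweep_interval(prep, 0, 50, 0, 1.0, 0.0, 8.0)
        np.testing.assert_array_equal(frag.d, [0, 0, 5, 0])
        assert frag.n_end == 45

    def test_flat_segment_has_no_events_only_censoring(self):
        prep = _prep_single_interval([0, 5, 10], [1.0, 1.0, 1.0], 30)
        frag = sweep_interval(prep, 0, 30, 3, 1.0, 0.0, 10.0)
        assert frag.d.sum() == 0
        assert frag.n_end == 27
        assert len(frag.applied_times) == 3

    def test_single_rounding_per_drop_after_step_control(self):
        # ten sub-clicks inside one drop would each round 0.4 events to 0;
        # after step control the drop rounds once to 4
        t_raw = np.concatenate([[0.0], np.full(10, 5.0), [9.0]])
        s_raw = np.concatenate([[1.0], 1.0 - 0.004 * np.arange(1, 11), [0.96]])
        prep = preprocess(make_points(t_raw, s_raw), total_n=100)
        ipd, est = reconstruct_ipd(prep)
        assert est.d_hat.sum() == 4


class TestFitInterval:
    def test_fixed_point_needs_no_extra_iterations(self):
        # curve and risk table agree: 10 events, no censoring
        prep = _prep_single_interval(
            [0, 4, 4, 9], [1.0, 1.0, 0.9, 0.9], 100, t_next=10, n_next=90
        )
        nc, frag = fit_interval(prep, 0, 100, 0, 1.0, 0.0, 10.0, target=90, cap=10)
        assert nc == 0 and frag.n_end == 90

    def test_boundary_blocked_underestimate_stays_at_zero(self):
        # the curve forces 10 events but the table says only 5 left the risk
        # set; an unconstrained update would drive the censor total negative
        prep = _prep_single_interval(
            [0, 4, 4, 9], [1.0, 1.0, 0.9, 0.9], 100, t_next=10, n_next=95
        )
        nc, frag = fit_interval(prep, 0, 100, 0, 1.0, 0.0, 10.0, target=95, cap=5)
        assert nc == 0
        assert frag.n_end == 90  # honest miss, not a negative censor count

    def test_recovers_known_censoring(self):
        # 20 at risk, 4 events and 4 censorings inside the interval
        rng = np.random.default_rng(5)
        t_ev = np.sort(rng.uniform(1, 9, 4))
        times, surv = [0.0], [1.0]
        S, n = 1.0, 20
        # true KM with 4 censorings interleaved (censor after each event)
        for j, te in enumerate(t_ev):
            times += [te, te]
            S_new = S * (1 - 1 / n)
            surv += [S, S_new]
            S = S_new
            n -= 2  # one event + one censoring before the next event time
        prep = _prep_single_interval(times, surv, 20, t_next=10, n_next=12)
        nc, frag = fit_interval(prep, 0, 20, 0, 1.0, 0.0, 10.0, target=12, cap=8)
        assert nc == 4
        assert frag.n_end == 12
        assert frag.d.sum() == 4


class TestReconstruct:
    def test_no_censoring_round_trip_is_exact(self):
        # a pure-event curve: IPD event times are exactly the drop times
        rng = np.random.default_rng(1)
        ev = np.sort(rng.exponential(6, 25))
        true_ipd = {"time": ev, "status": np.ones(25, int)}
        import pandas as pd

        fit = km_fit(pd.DataFrame(true_ipd))
        times, surv = [0.0], [1.0]
        prev = 1.0
        for tq, Sq in zip(fit.event_times, fit.survival):
            times += [tq, tq]
            surv += [prev, Sq]
            prev = Sq
        prep = _prep_single_interval(times, surv, 25)
        ipd, est = reconstruct_ipd(prep)
        assert (ipd.status == 1).all()
        np.testing.assert_allclose(np.sort(ipd.time), ev, rtol=1e-12)

    def test_risk_table_recovered_at_every_reporting_time(self, treat_arm, treat_recon):
        ipd, est = treat_recon
        np.testing.assert_array_equal(est.nrisk_est, treat_arm.risk.nrisk)

    def test_conservation_and_row_count(self, treat_prep, treat_recon):
        ipd, est = treat_recon
        assert len(ipd) == treat_prep.total_n
        total = est.d_hat.sum() + sum(len(c) for c in est.censor_times) + est.n_final
        assert total == treat_prep.nrisk[0]

    def test_at_risk_balance_everywhere(self, treat_recon):
        _, est = treat_recon
        n, d, c = est.n_hat, est.d_hat, est.cens_hat
        np.testing.assert_array_equal(n[1:], n[:-1] - d[:-1] - c[:-1])

    def test_internal_km_matches_km_of_output(self, treat_prep, treat_recon):
        ipd, est = treat_recon
        fit = km_fit(ipd)
        t = treat_prep.points.times
        drops = np.flatnonzero(est.d_hat > 0)
        np.testing.assert_allclose(
            np.atleast_1d(surv_at(fit, t[drops])), est.S_km[drops], atol=1e-10
        )

    def test_estimator_interface(self, treat_arm):
        rec = KaplanMeierReconstructor(
            trisk=list(treat_arm.risk.trisk), nrisk=list(treat_arm.risk.nrisk),
            arm="radio",
        )
        rec.fit(treat_arm.points.to_array())
        assert set(rec.ipd_.columns) == {"time", "status", "arm"}
        assert (rec.ipd_.arm == "radio").all()
        assert rec.score() > -0.05
        assert rec.get_params()["max_iter"] == 10_000

    def test_total_events_constrains_final_interval(self):
        # one interval, curve flat at the end: without tot_events nothing is
        # censored early; with it, the events budget seeds tail censoring
        times = [0, 2, 2, 10]
        surv = [1.0, 1.0, 0.9, 0.9]
        prep = _prep_single_interval(times, surv, 50)
        ipd_a, est_a = reconstruct_ipd(prep)
        assert est_a.ncensor.sum() == 0
        ipd_b, est_b = reconstruct_ipd(prep, tot_events=5)
        # censors placed before the drop shrink the risk set, so the event
        # total matches the budget within rounding
        assert abs(est_b.d_hat.sum() - 5) <= 1
        assert est_b.ncensor.sum() >= 40


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10**6),
    n0_extra=st.integers(0, 40),
    n_t=st.integers(2, 6),
)
def test_counts_never_negative_on_arbitrary_risk_tables(seed, n0_extra, n_t):
    """Box constraints keep every count non-negative even when the risk
    table is inconsistent with the digitized curve."""
    rng = np.random.default_rng(seed)
    n_pts = rng.integers(6, 25)
    t = np.sort(rng.uniform(0, 50, n_pts))
    s = np.sort(rng.uniform(0.05, 1.0, n_pts))[::-1]
    drops = int((np.diff(np.minimum.accumulate(s)) < 0).sum())
    trisk = np.unique(np.concatenate([[0.0], rng.uniform(1, 49, n_t - 1)]))
    n0 = drops + 1 + n0_extra
    nrisk = np.sort(rng.integers(1, n0 + 1, len(trisk)))[::-1]
    nrisk[0] = n0
    prep = preprocess(make_points(t, s), risk=RiskTable(trisk, nrisk))
    ipd, est = reconstruct_ipd(prep)
    assert np.all(est.d_hat >= 0)
    assert np.all(est.cens_hat >= 0)
    assert np.all(est.n_hat >= 0)
    assert np.all(est.ncensor >= 0)
    assert est.n_final >= 0
    total = est.d_hat.sum() + sum(len(c) for c in est.censor_times) + est.n_final
    assert total == n0
    assert len(ipd) == n0
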