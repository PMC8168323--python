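"""Survival-analysis primitives used by the assessment and reporting layers.

Product-limit estimation, Greenwood standard errors, Nelson-Aalen cumulative
hazard, survival quantiles, the two-sample log-rank test and proportional-
hazards hazard ratios (Efron tie handling, which matters here because
reconstructed data carry heavy event ties at the drop times), plus a
stratified percentile bootstrap for the hazard-ratio interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .exceptions import InvalidInputError

__all__ = [
    "KMFit",
    "km_fit",
    "surv_at",
    "quantile_time",
    "cumulative_hazard",
    "logrank_test",
    "hazard_ratio",
    "bootstrap_hr_ci",
    "survreport",
    "SurvReport",
]

Z95 = 1.959963984540054


def _extract(ipd) -> tuple[np.ndarray, np.ndarray]:
    """Pull (time, status) arrays out of a DataFrame or a pair of arrays."""
    if isinstance(ipd, pd.DataFrame):
        return ipd["time"].to_numpy(float), ipd["status"].to_numpy(int)
    t, e = ipd
    return np.asarray(t, float), np.asarray(e, int)


@dataclass
class KMFit:
    """Product-limit fit over the distinct event times of one arm.

    ``n_risk[q+1] = n_risk[q] - n_events[q] - n_censored[q]`` by
    construction; ``survival`` is right-continuous and non-increasing with
    ``S = 1`` before the first event time.
    """

    event_times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    cumhaz: np.ndarray
    n_subjects: int = 0
    max_time: float = field(default=np.nan)


def km_fit(ipd) -> KMFit:
    """Kaplan-Meier product-limit estimate for a single arm.

    Ties of events and censorings at the same time are resolved events-
    first.  The variance is Greenwood's ``S^2 * sum d/(n(n-d))``; the
    cumulative hazard accumulates the Nelson-Aalen increments ``d/n``.
    """
    t, e = _extract(ipd)
    if t.size == 0:
        raise InvalidInputError("empty patient table")
    if np.any(t < 0):
        raise InvalidInputError("negative times in patient table")

    kmf = KaplanMeierFitter().fit(t, e)
    tbl = kmf.event_table  # at_risk / observed / censored per distinct time
    ev = tbl[tbl["observed"] > 0]
    tq = ev.index.to_numpy(float)
    nq = ev["at_risk"].to_numpy(int)
    dq = ev["observed"].to_numpy(int)

    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.cumprod(1.0 - dq / nq)
        gw = np.where(nq > dq, dq / (nq * (nq - dq.astype(float))), 0.0)
        se = S * np.sqrt(np.cumsum(gw))
    cumhaz = np.cumsum(dq / nq)

    # censored between consecutive event times, from the balance relation
    cq = np.empty_like(nq)
    if nq.size:
        cq[:-1] = nq[:-1] - dq[:-1] - nq[1:]
        cq[-1] = nq[-1] - dq[-1]  # everyone left after the last event exits censored
    return KMFit(
        event_times=tq,
        n_risk=nq,
        n_events=dq,
        n_censored=cq,
        survival=S,
        se=se,
        cumhaz=cumhaz,
        n_subjects=int(t.size),
        max_time=float(t.max()),
    )


def surv_at(fit: KMFit, t) -> np.ndarray | float:
    """Right-continuous step lookup of the survival estimate at time(s) t."""
    t_arr = np.atleast_1d(np.asarray(t, float))
    idx = np.searchsorted(fit.event_times, t_arr, side="right")
    S = np.concatenate([[1.0], fit.survival])
    out = S[idx]
    return out if np.ndim(t) else float(out[0])


def se_at(fit: KMFit, t) -> np.ndarray | float:
    """Greenwood standard error at time(s) t (0 before the first event)."""
    t_arr = np.atleast_1d(np.asarray(t, float))
    idx = np.searchsorted(fit.event_times, t_arr, side="right")
    se = np.concatenate([[0.0], fit.se])
    out = se[idx]
    return out if np.ndim(t) else float(out[0])


def quantile_time(fit: KMFit, s: float) -> float | None:
    """Smallest event time at which survival falls to ``s`` or below.

    Returns ``None`` when the curve never reaches ``s`` ("not reached").
    """
    if not 0 < s < 1:
        raise InvalidInputError("survival level s must lie strictly between 0 and 1")
    hit = np.flatnonzero(fit.survival <= s)
    return float(fit.event_times[hit[0]]) if hit.size else None


def cumulative_hazard(fit: KMFit) -> np.ndarray:
    """Nelson-Aalen cumulative hazard at the event times."""
    return fit.cumhaz.copy()


def logrank_test(ipd1, ipd2) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) and two-sided p-value."""
    t1, e1 = _extract(ipd1)
    t2, e2 = _extract(ipd2)
    if t1.size == 0 or t2.size == 0:
        raise InvalidInputError("both arms must be non-empty")
    if e1.sum() + e2.sum() == 0:
        raise InvalidInputError("no events in either arm; the log-rank test is undefined")
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


def hazard_ratio(ipd1, ipd2) -> tuple[float, float, tuple[float, float]]:
    """Arm-1-versus-arm-2 hazard ratio from the Cox partial likelihood.

    Efron tie handling; Wald standard error on the log scale and the
    corresponding 95% confidence interval.
    """
    t1, e1 = _extract(ipd1)
    t2, e2 = _extract(ipd2)
    if e1.sum() < 1 or e2.sum() < 1:
        raise InvalidInputError("both arms need at least one event for a hazard ratio")
    df = pd.DataFrame(
        {
            "time": np.concatenate([t1, t2]),
            "status": np.concatenate([e1, e2]),
            "group": np.concatenate([np.ones(t1.size), np.zeros(t2.size)]),
        }
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="status")
    except Exception as exc:  # monotone likelihood and friends
        warnings.warn(f"Cox model did not converge cleanly: {exc}", UserWarning, stacklevel=2)
        raise
    log_hr = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    ci = (float(np.exp(log_hr - Z95 * se)), float(np.exp(log_hr + Z95 * se)))
    return float(np.exp(log_hr)), se, ci


def bootstrap_hr_ci(
    ipd1, ipd2, B: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """Percentile 95% bootstrap interval for the hazard ratio.

    Resamples patients with replacement within each arm (stratified), so
    arm sizes are preserved.  Replicates in which an arm loses all its
    events are skipped.
    """
    if B < 100:
        raise InvalidInputError("use at least 100 bootstrap replicates")
    t1, e1 = _extract(ipd1)
    t2, e2 = _extract(ipd2)
    rng = np.random.default_rng(seed)
    hrs = []
    skipped = 0
    for _ in range(B):
        i1 = rng.integers(0, t1.size, t1.size)
        i2 = rng.integers(0, t2.size, t2.size)
        if e1[i1].sum() < 1 or e2[i2].sum() < 1:
            skipped += 1
            continue
        try:
            hr, _, _ = hazard_ratio((t1[i1], e1[i1]), (t2[i2], e2[i2]))
        except Exception:
            skipped += 1
            continue
        hrs.append(hr)
    if skipped:
        warnings.warn(f"{skipped} degenerate bootstrap replicate(s) skipped", UserWarning, stacklevel=2)
    if len(hrs) < B // 2:
        raise InvalidInputError("too many degenerate bootstrap replicates")
    lo, hi = np.percentile(hrs, [2.5, 97.5])
    return float(lo), float(hi)


def _loglog_ci(S: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """95% CI for landmark survival on the log(-log) scale (stays in [0,1])."""
    S = np.asarray(S, float)
    se = np.asarray(se, float)
    lo = np.empty_like(S)
    hi = np.empty_like(S)
    interior = (S > 0) & (S < 1) & (se > 0)
    lo[~interior] = S[~interior]
    hi[~interior] = S[~interior]
    Si = S[interior]
    theta_se = se[interior] / (Si * np.abs(np.log(Si)))
    lo[interior] = Si ** np.exp(Z95 * theta_se)
    hi[interior] = Si ** np.exp(-Z95 * theta_se)
    return lo, hi


@dataclass
class SurvReport:
    """Secondary-analysis summary for one or two reconstructed arms."""

    arms: list
    landmarks: list           # one DataFrame per arm: time, survival, se, lo, hi
    quantiles: list           # one dict per arm: s -> time or None
    cumhaz: list              # one DataFrame per arm: time, cumhaz
    logrank_stat: float | None = None
    logrank_p: float | None = None
    hr: float | None = None
    hr_se_log: float | None = None
    hr_ci: tuple | None = None

    def to_dict(self) -> dict:
        out = {
            "arms": list(self.arms),
            "landmarks": [df.to_dict(orient="list") for df in self.landmarks],
            "quantile_times": [
                {str(k): v for k, v in q.items()} for q in self.quantiles
            ],
            "cumulative_hazard": [df.to_dict(orient="list") for df in self.cumhaz],
        }
        if self.hr is not None:
            out["hazard_ratio"] = {
                "hr": self.hr,
                "se_log_hr": self.hr_se_log,
                "ci95": list(self.hr_ci),
            }
        if self.logrank_stat is not None:
            out["logrank"] = {"statistic": self.logrank_stat, "p_value": self.logrank_p}
        return out

    def to_text(self) -> str:
        lines = []
        for a, arm in enumerate(self.arms):
            lines.append(f"Arm {arm}")
            lines.append("  Landmark survival (95% CI):")
            for _, row in self.landmarks[a].iterrows():
                lines.append(
                    f"    t={row['time']:g}: S={row['survival']:.3f} "
                    f"(se {row['se']:.3f}, CI {row['lo']:.3f}-{row['hi']:.3f})"
                )
            lines.append("  Survival-level crossing times:")
            for s_level, tt in self.quantiles[a].items():
                val = "not reached" if tt is None else f"{tt:g}"
                lines.append(f"    S<={s_level}: {val}")
        if self.logrank_stat is not None:
            lines.append(
                f"Log-rank: chi2={self.logrank_stat:.3f}, p={self.logrank_p:.4g}"
            )
        if self.hr is not None:
            lines.append(
                f"Hazard ratio (arm {self.arms[0]} vs {self.arms[1]}): "
                f"{self.hr:.3f} (95% CI {self.hr_ci[0]:.3f}-{self.hr_ci[1]:.3f})"
            )
        return "\n".join(lines)


def survreport(
    ipd1,
    ipd2=None,
    arms: int | None = None,
    interval: float = 6.0,
    s=(0.5,),
) -> SurvReport:
    """Landmark survival, quantile times, log-rank and HR for 1-2 arms.

    ``interval`` sets the landmark grid (every 6 months by default); ``s``
    lists the survival levels whose crossing times are wanted (0.5 gives
    the median).  With two arms the log-rank test and the hazard ratio of
    arm 1 versus arm 2 are included.
    """
    tables = [ipd1] + ([ipd2] if ipd2 is not None else [])
    if arms is not None and arms != len(tables):
        raise InvalidInputError(f"arms={arms} but {len(tables)} table(s) supplied")
    if interval <= 0:
        raise InvalidInputError("landmark interval must be positive")

    labels, landmarks, quantiles, cumhaz = [], [], [], []
    for a, ipd in enumerate(tables):
        if isinstance(ipd, pd.DataFrame) and "arm" in ipd.columns and len(ipd):
            labels.append(ipd["arm"].iloc[0])
        else:
            labels.append(a)
        fit = km_fit(ipd)
        grid = np.arange(interval, fit.max_time + 1e-9, interval)
        S = np.atleast_1d(surv_at(fit, grid))
        SE = np.atleast_1d(se_at(fit, grid))
        lo, hi = _loglog_ci(S, SE)
        landmarks.append(
            pd.DataFrame({"time": grid, "survival": S, "se": SE, "lo": lo, "hi": hi})
        )
        quantiles.append({float(level): quantile_time(fit, float(level)) for level in s})
        cumhaz.append(pd.DataFrame({"time": fit.event_times, "cumhaz": fit.cumhaz}))

    report = SurvReport(arms=labels, landmarks=landmarks, quantiles=quantiles, cumhaz=cumhaz)
    if len(tables) == 2:
        report.logrank_stat, report.logrank_p = logrank_test(ipd1, ipd2)
        report.hr, report.hr_se_log, report.hr_ci = hazard_ratio(ipd1, ipd2)
    return report


def ks_survival_comparison(s_read: np.ndarray, s_est: np.ndarray) -> tuple[float, float]:
    """Two-sample KS comparison of read-in vs estimated survival values."""
    res = stats.ks_2samp(np.asarray(s_read, float), np.asarray(s_est, float))
    return float(res.statistic), float(res.pvalue)
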