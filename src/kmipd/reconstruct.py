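"""Iterative reconstruction of individual patient data from a digitized K-M curve.

Given the cleaned, partitioned coordinates and a reported number-at-risk
table, the algorithm walks the reporting intervals.  Within each interval it
guesses a censor total, spreads the censorings uniformly over the interval
(constant-censoring assumption), sweeps the coordinates computing event
counts from the product-limit relation

    d_k = round( n_k * (1 - S_k / S_last) ),

where ``S_last`` is the running K-M estimate at the last coordinate with an
event, and then adjusts the censor total by the discrepancy between the
estimated and the reported number at risk at the start of the next interval.
The censor total is box-constrained to ``[0, nrisk_i - nrisk_{i+1}]``, which
is what keeps every estimated count non-negative and the iteration finite
(an unconstrained version of the same update can report negative censor
totals on dense risk tables).

The last interval has no reported target; its censor total is seeded from
the average censoring rate observed so far and, when the total number of
events is known, from the remaining events budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateCurveError,
    InvalidInputError,
    ReconstructionWarning,
)
from .preprocess import (
    DEFAULT_FENCE_K,
    CurvePoints,
    PreprocessedCurve,
    RiskTable,
    preprocess,
)

__all__ = [
    "CountEstimates",
    "KaplanMeierReconstructor",
    "init_censor_interval",
    "censor_times_for_interval",
    "sweep_interval",
    "fit_interval",
    "last_interval_censor_init",
    "reconstruct_ipd",
]

DEFAULT_MAX_ITER = 10_000


def round_half(x: float) -> int:
    """Round half away from zero (fixed convention for all count roundings)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class CountEstimates:
    """Per-coordinate and per-interval counts produced by the reconstruction.

    ``n_hat[k]`` is the number at risk just before coordinate ``k``;
    ``d_hat``/``cens_hat`` are the event and censor counts attributed to the
    coordinate; ``S_km`` is the running product-limit estimate after the
    coordinate.  ``ncensor[i]`` is the censor total applied in interval
    ``i`` and ``censor_times[i]`` the times actually assigned.
    ``n_final`` patients remain at risk past the last coordinate (they are
    emitted as censored at the last time).
    """

    n_hat: np.ndarray
    d_hat: np.ndarray
    cens_hat: np.ndarray
    S_km: np.ndarray
    ncensor: np.ndarray
    censor_times: list
    nrisk_est: np.ndarray
    n_final: int
    trisk: np.ndarray = field(default_factory=lambda: np.array([]))
    nrisk: np.ndarray = field(default_factory=lambda: np.array([]))
    lower: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    upper: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def audit_table(self) -> pd.DataFrame:
        """Per-interval reconciliation table (1-based point indices)."""
        I = len(self.trisk)
        events = [
            int(self.d_hat[self.lower[i] : self.upper[i] + 1].sum()) if self.upper[i] >= self.lower[i] else 0
            for i in range(I)
        ]
        return pd.DataFrame(
            {
                "interval": np.arange(1, I + 1),
                "lower": self.lower + 1,
                "upper": self.upper + 1,
                "trisk": self.trisk,
                "nrisk": self.nrisk,
                "nrisk_est": self.nrisk_est,
                "ncensor": self.ncensor,
                "events": events,
            }
        )


def init_censor_interval(
    nrisk_i: int, S_lo_i: float, S_lo_next: float, nrisk_next: int
) -> int:
    """Initial censor total for an interval from the survival drop across it.

    ``round(nrisk_i * S_lo_next / S_lo_i) - nrisk_next`` clamped to the
    admissible box ``[0, nrisk_i - nrisk_next]``; the product is the number
    that would remain at risk were there no censoring.
    """
    if S_lo_i <= 0:
        raise DegenerateCurveError(
            "survival is zero at the interval start but a later number at risk is reported"
        )
    nocensor = round_half(nrisk_i * (S_lo_next / S_lo_i))
    return int(np.clip(nocensor - nrisk_next, 0, max(nrisk_i - nrisk_next, 0)))


def censor_times_for_interval(t_lo: float, t_hi: float, ncensor: int) -> np.ndarray:
    """Censoring times spread evenly over (t_lo, t_hi).

    ``t_m = t_lo + m * (t_hi - t_lo) / (ncensor + 1)`` for ``m = 1..ncensor``
    (constant censoring rate within the interval).
    """
    if ncensor <= 0:
        return np.array([])
    if t_hi <= t_lo:
        # zero-length interval: nothing can be placed strictly inside
        return np.array([])
    m = np.arange(1, ncensor + 1, dtype=float)
    return t_lo + m * (t_hi - t_lo) / (ncensor + 1)


@dataclass
class _IntervalFragment:
    d: np.ndarray            # events per coordinate in the interval
    cens: np.ndarray         # censors applied per coordinate
    n_at: np.ndarray         # at-risk just before each coordinate
    S_traj: np.ndarray       # running KM estimate after each coordinate
    n_end: int               # at-risk after the interval
    S_km_end: float
    applied_times: np.ndarray


def sweep_interval(
    prep: PreprocessedCurve,
    i: int,
    n_start: int,
    ncensor_i: int,
    S_km_in: float,
    t_lo: float,
    t_hi: float,
) -> _IntervalFragment:
    """One pass over interval ``i`` with a fixed censor total.

    Walks coordinates ``lower[i]..upper[i]`` computing event counts from the
    product-limit relation (rounded once per coordinate, clamped to
    ``[0, n_k]``), counts the evenly-spread censor times falling in each
    ``[T_k, T_{k+1})`` window, and advances the at-risk count.  The running
    K-M estimate is updated multiplicatively only at coordinates with
    events, so flat digitized segments leave it untouched.

    When the interval's curve terminates at zero survival, one patient is
    reserved past the censor placement until the terminal drop: a
    product-limit curve can only reach zero through an event, so censoring
    must never exhaust the risk set before the last coordinate.
    """
    lo, up = int(prep.lower[i]), int(prep.upper[i])
    tc = censor_times_for_interval(t_lo, t_hi, ncensor_i)

    n = int(n_start)
    S_km = float(S_km_in)
    if lo > up:  # no coordinates: pure-censoring interval
        c_app = min(len(tc), n)
        applied = tc[:c_app]
        return _IntervalFragment(
            d=np.array([], dtype=int),
            cens=np.array([], dtype=int),
            n_at=np.array([], dtype=int),
            S_traj=np.array([]),
            n_end=n - c_app,
            S_km_end=S_km,
            applied_times=applied,
        )

    t = prep.points.times
    s = prep.points.surv
    m = up - lo + 1
    d = np.zeros(m, dtype=int)
    cens = np.zeros(m, dtype=int)
    n_at = np.zeros(m, dtype=int)
    S_traj = np.zeros(m)
    applied: list[float] = []

    # index of the terminal drop to zero survival, if the curve has one here
    zero_hits = np.flatnonzero(s[lo : up + 1] <= 0.0)
    k_zero = lo + zero_hits[0] if zero_hits.size else None

    for j, k in enumerate(range(lo, up + 1)):
        n_at[j] = n
        if n > 0 and S_km > 0:
            d_k = round_half(n * (1.0 - s[k] / S_km))
            d_k = int(np.clip(d_k, 0, n))
        else:
            d_k = 0
        if d_k > 0:
            S_km *= 1.0 - d_k / n
            if n - d_k == 0:
                S_km = 0.0
        d[j] = d_k
        right = t[k + 1] if k < up else t_hi
        in_bin = tc[(tc >= t[k]) & (tc < right)] if tc.size else tc
        room = n - d_k
        if k_zero is not None and k < k_zero:
            room = max(room - 1, 0)  # keep someone at risk for the drop to zero
        c_k = min(len(in_bin), room)
        applied.extend(in_bin[:c_k])
        cens[j] = c_k
        n = n - d_k - c_k
        S_traj[j] = S_km

    return _IntervalFragment(
        d=d,
        cens=cens,
        n_at=n_at,
        S_traj=S_traj,
        n_end=n,
        S_km_end=S_km,
        applied_times=np.asarray(applied),
    )


def fit_interval(
    prep: PreprocessedCurve,
    i: int,
    n_start: int,
    ncensor_init: int,
    S_km_in: float,
    t_lo: float,
    t_hi: float,
    target: int,
    cap: int,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[int, _IntervalFragment]:
    """Iterate the censor total of interval ``i`` toward the reported target.

    After each sweep the censor total is adjusted by the signed discrepancy
    between the estimated and the reported number at risk at the interval
    end, as long as it can still move inside the admissible box
    ``[0, cap]``.  The update can cycle between neighbouring totals under
    rounding; tried totals are memoized and on a revisit the bracket of
    tried values is scanned exhaustively, returning the total minimizing the
    absolute discrepancy (ties broken toward fewer censorings).
    """
    cap = max(int(cap), 0)
    nc = int(np.clip(ncensor_init, 0, cap))
    tried: dict[int, _IntervalFragment] = {}

    def err(frag: _IntervalFragment) -> int:
        return frag.n_end - target

    for _ in range(max_iter):
        if nc in tried:
            lo_b, hi_b = min(tried), max(tried)
            for c in range(lo_b, hi_b + 1):
                if c not in tried:
                    tried[c] = sweep_interval(prep, i, n_start, c, S_km_in, t_lo, t_hi)
            break
        frag = sweep_interval(prep, i, n_start, nc, S_km_in, t_lo, t_hi)
        tried[nc] = frag
        e = err(frag)
        if e == 0:
            return nc, frag
        if e > 0 and nc < cap:          # over-estimate: add censorings
            nc = min(nc + e, cap)
        elif e < 0 and nc > 0:          # under-estimate: remove censorings
            nc = max(nc + e, 0)
        else:                           # boundary reached: best we can do
            break
    else:
        warnings.warn(
            f"interval {i + 1}: censor-total iteration cap reached; best iterate kept",
            ReconstructionWarning,
            stacklevel=2,
        )

    best = min(tried, key=lambda c: (abs(err(tried[c])), c))
    return best, tried[best]


def last_interval_censor_init(
    nrisk_last: int,
    n_avail: int,
    total_censored: int,
    elapsed: float,
    last_length: float,
    endpts: int = 0,
    tot_events: int | None = None,
    d_sum_prev: int = 0,
) -> int:
    """Seed the censor total of the final interval (no reported target).

    Uses ``min(average censoring rate * interval length, nrisk_I - endpts -
    remaining events budget)``, where the average rate is the total censored
    so far per unit of elapsed reporting time.  Without a total-events count
    the budget term degenerates to ``nrisk_I - endpts``.  In single-interval
    mode (no elapsed history) the rate is unknown: with a total-events count
    the budget alone seeds the total, otherwise no censoring is assumed.
    """
    if tot_events is not None:
        bound = nrisk_last - endpts - max(tot_events - d_sum_prev, 0)
    else:
        bound = nrisk_last - endpts
    if elapsed > 0:
        rate_term = (total_censored / elapsed) * last_length
        nc = min(rate_term, bound)
    else:
        nc = bound if tot_events is not None else 0.0
    nc = round_half(max(float(nc), 0.0))
    return int(np.clip(nc, 0, max(n_avail - max(endpts, 0), 0)))


def reconstruct_ipd(
    prep: PreprocessedCurve,
    arm=0,
    tot_events: int | None = None,
    endpts: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[pd.DataFrame, CountEstimates]:
    """Reconstruct one arm's individual patient data from a cleaned curve.

    Returns ``(ipd, estimates)`` where ``ipd`` has one row per patient with
    columns ``time`` (months, on the published axis), ``status`` (1 event,
    0 censored) and ``arm``, and ``estimates`` carries the full per-
    coordinate audit trail.  Row count equals the initial number at risk:
    events are placed at their drop times, censorings at the evenly-spread
    censor times, and patients still at risk after the last coordinate are
    censored at the last time.
    """
    t = prep.points.times
    s = prep.points.surv
    N = prep.points.n
    I = prep.n_intervals
    trisk, nrisk = prep.trisk, prep.nrisk

    n_drops = int((np.diff(s) < 0).sum())
    if nrisk[0] < 1:
        raise InvalidInputError("initial number at risk must be positive")
    if nrisk[0] < n_drops:
        raise InvalidInputError(
            f"initial number at risk ({nrisk[0]}) is smaller than the number of "
            f"survival drops ({n_drops}); inputs are inconsistent"
        )

    # interval boundary times: first coordinate of the interval when it has
    # one, else the reported risk time; last interval ends at the last point
    t_start = np.where(
        prep.lower <= prep.upper,
        t[np.minimum(prep.lower, N - 1)],
        trisk,
    ).astype(float)
    t_end = np.empty(I)
    t_end[:-1] = t_start[1:]
    t_end[-1] = t[-1]

    # survival at each interval start (carried forward over empty intervals)
    S_start = np.empty(I)
    last_s = 1.0
    for i in range(I):
        if prep.lower[i] <= prep.upper[i]:
            last_s = s[prep.lower[i]]
        S_start[i] = last_s

    n_hat = np.zeros(N, dtype=int)
    d_hat = np.zeros(N, dtype=int)
    cens_hat = np.zeros(N, dtype=int)
    S_arr = np.ones(N)
    ncensor = np.zeros(I, dtype=int)
    censor_times: list[np.ndarray] = []
    nrisk_est = np.zeros(I, dtype=int)

    n_cur = int(nrisk[0])
    S_km = 1.0
    total_censored = 0
    d_sum = 0

    for i in range(I):
        nrisk_est[i] = n_cur
        if i < I - 1:
            target = int(nrisk[i + 1])
            cap = int(nrisk[i]) - target
            nc0 = init_censor_interval(int(nrisk[i]), S_start[i], S_start[i + 1], target)
            nc, frag = fit_interval(
                prep, i, n_cur, nc0, S_km, t_start[i], t_end[i], target, cap, max_iter
            )
        else:
            elapsed = float(trisk[-1] - trisk[0])
            nc = last_interval_censor_init(
                int(nrisk[-1]),
                n_cur,
                total_censored,
                elapsed,
                float(t_end[-1] - t_start[-1]),
                endpts=endpts,
                tot_events=tot_events,
                d_sum_prev=d_sum,
            )
            frag = sweep_interval(prep, i, n_cur, nc, S_km, t_start[i], t_end[i])

        lo, up = int(prep.lower[i]), int(prep.upper[i])
        if lo <= up:
            sl = slice(lo, up + 1)
            n_hat[sl] = frag.n_at
            d_hat[sl] = frag.d
            cens_hat[sl] = frag.cens
            S_arr[sl] = frag.S_traj
        applied = frag.applied_times
        ncensor[i] = len(applied)
        censor_times.append(applied)
        total_censored += len(applied)
        d_sum += int(frag.d.sum())
        n_cur = frag.n_end
        S_km = frag.S_km_end

    n_final = n_cur
    total = d_sum + total_censored + n_final
    if total != int(nrisk[0]):  # conservation holds by construction
        raise RuntimeError(
            f"internal inconsistency: {d_sum} events + {total_censored} censored "
            f"+ {n_final} remaining != {nrisk[0]} at risk"
        )

    rows_t = np.concatenate(
        [
            np.repeat(t, d_hat),
            np.concatenate(censor_times) if censor_times else np.array([]),
            np.full(n_final, t[-1]),
        ]
    )
    rows_e = np.concatenate(
        [
            np.ones(d_sum, dtype=int),
            np.zeros(total_censored + n_final, dtype=int),
        ]
    )
    order = np.argsort(rows_t, kind="stable")
    ipd = pd.DataFrame({"time": rows_t[order], "status": rows_e[order]})
    ipd["arm"] = arm

    est = CountEstimates(
        n_hat=n_hat,
        d_hat=d_hat,
        cens_hat=cens_hat,
        S_km=S_arr,
        ncensor=ncensor,
        censor_times=censor_times,
        nrisk_est=nrisk_est,
        n_final=n_final,
        trisk=trisk.copy(),
        nrisk=nrisk.copy(),
        lower=prep.lower.copy(),
        upper=prep.upper.copy(),
    )
    return ipd, est


class KaplanMeierReconstructor(BaseEstimator):
    """Sklearn-style estimator: digitized K-M coordinates in, patient data out.

    ``fit`` accepts either an (N, 2) array of raw (time, survival) pairs —
    in which case the cleaning pipeline runs first — or an already
    :class:`~kmipd.preprocess.PreprocessedCurve`.

    Parameters
    ----------
    trisk, nrisk : sequences, optional
        Reported number-at-risk table (times and counts).
    total_n : int, optional
        Total patients; required when no risk table is available.
    tot_events : int, optional
        Total number of events, when reported (improves the final interval).
    endpts : int, default 0
        Number at risk reported at the very end of follow-up.
    arm : label, default 0
        Arm identifier written into the reconstructed table.
    fence_k : float, default 3.0
        Tukey fence multiplier for preprocessing.
    max_iter : int, default 10000
        Cap on censor-total iterations per interval.

    Attributes
    ----------
    prep_ : PreprocessedCurve
        The cleaned curve actually reconstructed.
    ipd_ : pandas.DataFrame
        Reconstructed patient records (time, status, arm).
    estimates_ : CountEstimates
        Per-coordinate/per-interval audit counts.

    Examples
    --------
    >>> rec = KaplanMeierReconstructor(trisk=[0, 12, 24], nrisk=[100, 60, 25])
    >>> rec.fit(coords)          # doctest: +SKIP
    >>> rec.ipd_.head()          # doctest: +SKIP
    """

    def __init__(
        self,
        trisk=None,
        nrisk=None,
        total_n=None,
        tot_events=None,
        endpts=0,
        arm=0,
        fence_k=DEFAULT_FENCE_K,
        max_iter=DEFAULT_MAX_ITER,
    ):
        self.trisk = trisk
        self.nrisk = nrisk
        self.total_n = total_n
        self.tot_events = tot_events
        self.endpts = endpts
        self.arm = arm
        self.fence_k = fence_k
        self.max_iter = max_iter

    def fit(self, X, y=None):
        if isinstance(X, PreprocessedCurve):
            prep = X
        else:
            risk = None
            if self.trisk is not None or self.nrisk is not None:
                risk = RiskTable(np.asarray(self.trisk, float), np.asarray(self.nrisk))
            prep = preprocess(X, risk=risk, total_n=self.total_n, fence_k=self.fence_k)
        self.prep_ = prep
        self.ipd_, self.estimates_ = reconstruct_ipd(
            prep,
            arm=self.arm,
            tot_events=self.tot_events,
            endpts=self.endpts,
            max_iter=self.max_iter,
        )
        return self

    def score(self, X=None, y=None) -> float:
        """Negative RMSE between reconstructed and read-in survival values."""
        from .assess import accuracy_summary

        if not hasattr(self, "ipd_"):
            raise RuntimeError("call fit before score")
        return -accuracy_summary(self.prep_, self.ipd_).rmse
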