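"""Cleaning of digitized Kaplan-Meier coordinates.

Raw points clicked off a published K-M curve arrive unordered, possibly on a
percent scale, with occasional extraction blunders and small monotonicity
violations.  This module turns them into a sorted, monotone, step-controlled
point set partitioned into the reporting intervals of the number-at-risk
table, which is the input the iterative reconstruction consumes.

The cleaning pipeline is: sort/normalize -> quartile-fence outlier removal ->
force monotonicity (running minimum) -> step control (keep only the top and
bottom point of each vertical drop) -> partition by risk times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    EmptyIntervalWarning,
    InvalidInputError,
    InvalidRiskTableError,
    MissingInputError,
)

__all__ = [
    "CurvePoints",
    "RiskTable",
    "PreprocessedCurve",
    "CurvePreprocessor",
    "normalize_and_sort",
    "tukey_outlier_filter",
    "force_monotone",
    "step_control",
    "partition_intervals",
    "preprocess",
]

#: Default Tukey fence multiplier.  A wide fence (3 rather than 1.5) is used
#: so that only gross extraction blunders are discarded.
DEFAULT_FENCE_K = 3.0

#: Survival values above this are taken to be percentages (a true survival
#: fraction never exceeds 1; percent-scale curves start near 100).
PERCENT_THRESHOLD = 1.5


@dataclass
class CurvePoints:
    """Ordered (time, survival) pairs digitized from a K-M curve.

    ``times`` are in the published axis units (typically months); ``surv``
    are survival probabilities, stored as fractions in [0, 1] once
    :func:`normalize_and_sort` has run.
    """

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.surv.shape:
            raise InvalidInputError("times and surv must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return self.times.size

    @classmethod
    def from_array(cls, X) -> "CurvePoints":
        """Build from an (N, 2) array-like of (time, survival) rows."""
        if isinstance(X, CurvePoints):
            return cls(X.times.copy(), X.surv.copy())
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[1] != 2:
            raise InvalidInputError("expected an (N, 2) array of (time, survival) pairs")
        return cls(A[:, 0], A[:, 1])

    def to_array(self) -> np.ndarray:
        return np.column_stack([self.times, self.surv])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


@dataclass
class RiskTable:
    """Reported number-at-risk table: counts ``nrisk`` at times ``trisk``."""

    trisk: np.ndarray
    nrisk: np.ndarray

    def __post_init__(self) -> None:
        self.trisk = np.asarray(self.trisk, dtype=float)
        self.nrisk = np.asarray(self.nrisk)
        if self.trisk.ndim != 1 or self.trisk.shape != self.nrisk.shape:
            raise InvalidRiskTableError("trisk and nrisk must have the same length")
        if self.trisk.size == 0:
            raise InvalidRiskTableError("risk table is empty")
        if not np.all(np.isfinite(self.trisk)):
            raise InvalidRiskTableError("risk times must be finite")
        if np.any(np.diff(self.trisk) <= 0):
            raise InvalidRiskTableError("risk times must be strictly increasing")
        if np.any(self.nrisk <= 0):
            raise InvalidRiskTableError("numbers at risk must be positive")
        if np.any(np.diff(self.nrisk) > 0):
            raise InvalidRiskTableError("numbers at risk must be non-increasing")
        self.nrisk = self.nrisk.astype(int)

    @property
    def n_intervals(self) -> int:
        return self.trisk.size


@dataclass
class PreprocessedCurve:
    """Cleaned coordinates plus the interval partition used by reconstruction.

    ``lower``/``upper`` hold, per interval, the (0-based, inclusive) index of
    the first and last cleaned point whose time falls in
    ``[trisk[i], trisk[i+1])`` (last interval closed on the right).  An
    empty interval is stored as ``upper[i] == lower[i] - 1`` so the index
    ranges still tile ``0..N-1`` contiguously.
    """

    points: CurvePoints
    trisk: np.ndarray
    nrisk: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    total_n: int
    scale_factor: float = 1.0
    has_risk_table: bool = True
    outlier_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_intervals(self) -> int:
        return len(self.trisk)

    def riskmat(self):
        """Interval bookkeeping table (1-based indices, as usually printed)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "interval": np.arange(1, self.n_intervals + 1),
                "lower": self.lower + 1,
                "upper": self.upper + 1,
                "trisk": self.trisk,
                "nrisk": self.nrisk,
            }
        )


def normalize_and_sort(
    points: CurvePoints, first_risk_time: float = 0.0
) -> tuple[CurvePoints, float]:
    """Sort by time, detect percent scale, and anchor the curve start.

    Returns the sorted points and the detected scale factor (1 or 100).  An
    anchor point ``(first_risk_time, 1.0)`` is prepended when the earliest
    digitized point already sits below 1 and no point exists at the first
    risk time, so the first product-limit factor is well defined.  Points
    digitized before the first risk time are dropped with a warning.
    """
    if points.n < 2:
        raise InvalidInputError("at least 2 coordinate pairs are required")
    if not (np.all(np.isfinite(points.times)) and np.all(np.isfinite(points.surv))):
        raise InvalidInputError("coordinates must be finite")
    if np.any(points.surv < 0) or np.any(points.times < 0):
        raise InvalidInputError("negative time or survival value in coordinates")

    order = np.argsort(points.times, kind="stable")
    t = points.times[order]
    s = points.surv[order]

    scale_factor = 1.0
    if s.max() > PERCENT_THRESHOLD:
        s = s / 100.0
        scale_factor = 100.0
    s = np.minimum(s, 1.0)  # digitization wobble can land slightly above 1

    keep = t >= first_risk_time
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} point(s) before the first risk time",
            UserWarning,
            stacklevel=2,
        )
        t, s = t[keep], s[keep]
        if t.size < 2:
            raise InvalidInputError("fewer than 2 points remain at or after the first risk time")

    if s[0] < 1.0 and t[0] > first_risk_time:
        t = np.concatenate([[first_risk_time], t])
        s = np.concatenate([[1.0], s])

    return CurvePoints(t, s), scale_factor


def tukey_outlier_filter(
    points: CurvePoints, k: float = DEFAULT_FENCE_K
) -> tuple[CurvePoints, np.ndarray]:
    """Remove extraction blunders using a quartile fence on survival increments.

    The fenced statistic is the successive increment ``S_k - S_{k-1}``; the
    fence is ``[Q1 - k*IQR, Q3 + k*IQR]``.  Because survival can never rise,
    the rule is direction-aware:

    * a point whose increment exceeds ``max(upper fence, 0)`` is a spike
      above the curve and is removed, unless it is itself the recovery from
      a below-fence spike at the previous point;
    * a point whose increment falls below ``min(lower fence, 0)`` is removed
      only when the next increment is positive — the curve "recovering"
      upward proves the point was off the curve, whereas a legitimate large
      drop is never followed by a rise.

    Returns the filtered points and the indices (into the input) removed.
    Curves with fewer than 4 points pass through unchanged.
    """
    if k <= 0:
        raise InvalidInputError("fence multiplier k must be positive")
    if points.n < 4:
        return CurvePoints(points.times.copy(), points.surv.copy()), np.array([], dtype=int)

    inc = np.diff(points.surv)  # inc[j] belongs to point j+1
    q1, q3 = np.percentile(inc, [25, 75])
    iqr = q3 - q1
    hi = max(q3 + k * iqr, 0.0)
    lo = min(q1 - k * iqr, 0.0)

    n = points.n
    remove = np.zeros(n, dtype=bool)
    for j, d in enumerate(inc):
        idx = j + 1
        if d > hi and not (j >= 1 and inc[j - 1] < lo):
            remove[idx] = True
        elif d < lo and idx < n - 1 and inc[j + 1] > 0:
            remove[idx] = True

    removed = np.flatnonzero(remove)
    return CurvePoints(points.times[~remove], points.surv[~remove]), removed


def force_monotone(points: CurvePoints) -> CurvePoints:
    """Clamp survival to a non-increasing sequence via running minimum."""
    return CurvePoints(points.times.copy(), np.minimum.accumulate(points.surv))


def step_control(points: CurvePoints) -> CurvePoints:
    """Keep only the first and last point of every vertical segment.

    Multiple clicks at the same time value describe one drop of the curve;
    reducing them to the top and bottom point makes the event count of the
    drop round exactly once during reconstruction, avoiding the
    round-to-zero under-estimate that sub-dividing a drop can cause.
    """
    t = points.times
    if t.size <= 2:
        return CurvePoints(t.copy(), points.surv.copy())
    keep = np.ones(t.size, dtype=bool)
    # interior of a run of equal times: same time before and after
    keep[1:-1] = ~((t[1:-1] == t[:-2]) & (t[1:-1] == t[2:]))
    return CurvePoints(t[keep], points.surv[keep])


def partition_intervals(
    points: CurvePoints,
    risk: RiskTable | None = None,
    total_n: int | None = None,
    scale_factor: float = 1.0,
    outlier_indices: np.ndarray | None = None,
) -> PreprocessedCurve:
    """Partition cleaned points into the risk-table reporting intervals.

    Interval ``i`` covers ``[trisk[i], trisk[i+1])``; the last interval is
    closed on the right at the last coordinate.  Ties at a boundary go to
    the later interval, matching "number at risk at the beginning of the
    interval".  Without a risk table a single interval spanning all points
    is created with ``nrisk[0] = total_n``.
    """
    if outlier_indices is None:
        outlier_indices = np.array([], dtype=int)
    t = points.times
    N = points.n
    if N < 2:
        raise InvalidInputError("at least 2 cleaned points are required")

    if risk is None:
        if total_n is None:
            raise MissingInputError("supply a risk table or the total number of patients")
        if total_n < 1:
            raise InvalidInputError("total_n must be a positive integer")
        return PreprocessedCurve(
            points=points,
            trisk=np.array([t[0]]),
            nrisk=np.array([int(total_n)]),
            lower=np.array([0]),
            upper=np.array([N - 1]),
            total_n=int(total_n),
            scale_factor=scale_factor,
            has_risk_table=False,
            outlier_indices=outlier_indices,
        )

    I = risk.n_intervals
    cut = np.searchsorted(t, risk.trisk, side="left")
    lower = cut.astype(int)
    upper = np.empty(I, dtype=int)
    upper[:-1] = lower[1:] - 1
    upper[-1] = N - 1
    empty = np.flatnonzero(upper < lower)
    if empty.size:
        warnings.warn(
            f"risk-table interval(s) {[int(i) + 1 for i in empty]} contain no digitized "
            "points; they are carried as pure-censoring intervals",
            EmptyIntervalWarning,
            stacklevel=2,
        )
    total = int(risk.nrisk[0])
    if total_n is not None and int(total_n) != total:
        warnings.warn(
            f"total_n={total_n} disagrees with nrisk[0]={total}; using the risk table",
            UserWarning,
            stacklevel=2,
        )
    return PreprocessedCurve(
        points=points,
        trisk=risk.trisk.copy(),
        nrisk=risk.nrisk.copy(),
        lower=lower,
        upper=upper,
        total_n=total,
        scale_factor=scale_factor,
        has_risk_table=True,
        outlier_indices=outlier_indices,
    )


def preprocess(
    raw,
    risk: RiskTable | None = None,
    total_n: int | None = None,
    fence_k: float = DEFAULT_FENCE_K,
) -> PreprocessedCurve:
    """Full cleaning pipeline from raw digitized coordinates.

    Applies :func:`normalize_and_sort`, :func:`tukey_outlier_filter`,
    :func:`force_monotone`, :func:`step_control` and
    :func:`partition_intervals`, in that order.

    Parameters
    ----------
    raw : array-like of shape (N, 2) or CurvePoints
        Digitized (time, survival) pairs; survival may be on a percent scale.
    risk : RiskTable, optional
        Reported number-at-risk table.
    total_n : int, optional
        Total patients; required when ``risk`` is absent.
    fence_k : float
        Tukey fence multiplier for outlier removal.
    """
    pts = CurvePoints.from_array(raw)
    first_t = float(risk.trisk[0]) if risk is not None else 0.0
    pts, scale = normalize_and_sort(pts, first_risk_time=first_t)
    pts, removed = tukey_outlier_filter(pts, k=fence_k)
    pts = force_monotone(pts)
    pts = step_control(pts)
    return partition_intervals(
        pts, risk=risk, total_n=total_n, scale_factor=scale, outlier_indices=removed
    )


class CurvePreprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping :func:`preprocess`.

    ``transform`` maps an (N, 2) array of raw digitized (time, survival)
    pairs to the cleaned (M, 2) array; the full interval bookkeeping for the
    data seen by ``fit`` is exposed through fitted attributes.

    Parameters
    ----------
    trisk, nrisk : sequences, optional
        Reported risk-table times and counts.
    total_n : int, optional
        Total patients (required when no risk table is given).
    fence_k : float, default 3.0
        Tukey fence multiplier.

    Attributes
    ----------
    curve_ : PreprocessedCurve
        Cleaned points plus interval partition for the fitted data.
    scale_factor_ : float
        1 or 100 depending on the detected input scale.
    outlier_indices_ : ndarray
        Indices of points removed by the quartile fence.
    """

    def __init__(self, trisk=None, nrisk=None, total_n=None, fence_k=DEFAULT_FENCE_K):
        self.trisk = trisk
        self.nrisk = nrisk
        self.total_n = total_n
        self.fence_k = fence_k

    def _risk(self) -> RiskTable | None:
        if self.trisk is None and self.nrisk is None:
            return None
        if self.trisk is None or self.nrisk is None:
            raise InvalidRiskTableError("trisk and nrisk must be given together")
        return RiskTable(np.asarray(self.trisk, float), np.asarray(self.nrisk))

    def fit(self, X, y=None):
        self.curve_ = preprocess(
            X, risk=self._risk(), total_n=self.total_n, fence_k=self.fence_k
        )
        self.scale_factor_ = self.curve_.scale_factor
        self.outlier_indices_ = self.curve_.outlier_indices
        self.n_intervals_ = self.curve_.n_intervals
        return self

    def transform(self, X):
        if not hasattr(self, "curve_"):
            raise RuntimeError("CurvePreprocessor must be fitted before transform")
        prep = preprocess(X, risk=self._risk(), total_n=self.total_n, fence_k=self.fence_k)
        return prep.points.to_array()
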