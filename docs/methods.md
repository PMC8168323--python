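# Methods

## Problem and model

A published Kaplan-Meier curve is a right-continuous step function
`S(t)` produced by the product-limit estimator

    S(t_q) = prod_{j<=q} (1 − d_j / n_j),        n_{q+1} = n_q − d_q − c_q,

over the distinct event times `t_q`, with `n_q` at risk, `d_q` events and
`c_q` censorings between event times. Digitizing the curve yields noisy
samples `(T_k, S_k)` of this step function; the number-at-risk table
`(trisk_i, nrisk_i)` printed beneath the plot pins down `n` at the interval
boundaries. Reconstruction inverts the estimator: find per-coordinate event
and censor counts that (a) reproduce the digitized survival values through
the product-limit relation and (b) agree with the reported at-risk counts
at every `trisk_i`.

The estimator is identified only up to the placement of censorings inside
an interval; we adopt the standard uniform-censoring assumption and spread
each interval's censorings evenly over its time span. Everything else
follows from the two constraints above.

## Preprocessing

Raw clicked coordinates are cleaned in a fixed order; each step repairs a
specific digitization failure mode:

1. **Sort / normalize.** Stable sort by time (so a drop digitized
   top-then-bottom keeps that order at tied times). Survival values with
   maximum above 1.5 are treated as percentages and divided by 100 — a
   genuine survival fraction never exceeds 1, while percent-scale curves
   start near 100, so the rule cannot misfire on realistic input. An
   anchor point `(trisk_1, 1.0)` is prepended when the first digitized
   point already sits below 1, so the first product-limit factor is well
   defined.
2. **Quartile fence** (multiplier k = 3, wide on purpose so only gross
   blunders are removed). The fenced statistic is the successive increment
   `S_k − S_{k−1}`. Because survival can never rise, the rule is
   direction-aware: a point is removed when its increment exceeds
   `max(Q3 + 3·IQR, 0)` (a spike above the curve) unless it is itself the
   recovery from a below-fence spike, or when its increment falls below
   `min(Q1 − 3·IQR, 0)` **and** the next increment is positive — the curve
   recovering upward proves the point was off the curve, whereas a
   legitimate large drop is never followed by a rise. A naive two-sided
   rule would delete real late-time drops (on a clean monotone curve the
   upper quartile of increments is ~0, so the lower fence lands on top of
   ordinary steps) and would make the pipeline non-idempotent after step
   control merges sub-drops into one large increment.
3. **Force monotonicity.** Running minimum over the survival values; no
   points are deleted, so dense information is kept for the count
   estimation.
4. **Step control.** Every maximal run of points sharing one time value is
   reduced to its first and last point. A drop digitized as s sub-points
   would otherwise round its event count s times; with sub-counts in
   [0.1, 0.5) every one rounds to zero and the at-risk count is
   under-estimated. Two points per vertical segment make the drop round
   exactly once.
5. **Partition.** Interval *i* covers `[trisk_i, trisk_{i+1})`, the last
   interval closed at the final coordinate; boundary ties go to the later
   interval, matching "at risk at the beginning of the interval". An
   interval containing no coordinates is kept with an empty index range
   (warning emitted) and handled as a pure-censoring interval during
   estimation. Without a risk table a single interval with
   `nrisk_1 = total_n` is used.

The pipeline is idempotent on the point set: re-running it on its own
output changes nothing. This is asserted property-style in the tests.

## Iterative count estimation

Within interval *i* (reported target `nrisk_{i+1}` available):

* **Initial censor total** (survival-drop heuristic):
  `round(nrisk_i · S_{start,i+1} / S_{start,i}) − nrisk_{i+1}`, clamped to
  the admissible box `[0, nrisk_i − nrisk_{i+1}]` before the first sweep.
* **Sweep.** Censor times `t_m = t_lo + m(t_hi − t_lo)/(ncensor_i + 1)`;
  per-coordinate censor counts by binning into `[T_k, T_{k+1})`; events
  `d_k = round(n_k (1 − S_k / S_last))` clamped to `[0, n_k]`, with
  `S_last` the running product-limit value at the most recent coordinate
  carrying an event (flat digitized segments therefore contribute no
  events and leave `S_last` untouched).
* **Adjustment.** `ncensor_i += (n̂ at interval end − nrisk_{i+1})`, while
  the over-estimate condition (end estimate above target and room left in
  the box) or the under-estimate condition (below target and
  `ncensor_i > 0`) holds. The box keeps every count non-negative and the
  iteration finite; an unconstrained version of the same update walks to
  negative censor totals on dense tables (re-demonstrated in the test
  suite). Rounding can make the update cycle between neighbouring totals,
  so tried totals are memoized; on a revisit the bracket of tried values
  is scanned and the total minimizing the absolute end-of-interval
  discrepancy is kept (ties toward fewer censorings). On small intervals
  this provably matches brute-force search over the box, which the tests
  check by enumeration.

**Last interval.** No target exists, so the censor total is seeded by
`min(rate · length, nrisk_I − endpts − remaining_events_budget)`, where
`rate` is total censorings so far per unit of elapsed reporting time, and
the budget term uses the published total event count when available
(otherwise it degenerates to `nrisk_I − endpts`). In single-interval mode
(no risk table) there is no elapsed history: with a total event count the
budget alone seeds the total; without one, no censoring is assumed and the
accuracy caveat applies — reconstruction without a risk table cannot
resolve censoring.

**Terminal drop to zero.** If the digitized curve ends at exactly
`S = 0`, the final drop must be an event of the entire remaining risk set;
the sweep therefore reserves one patient through the censor bins until the
terminal coordinate. Without this, evenly-spread censoring can exhaust the
risk set just before the last drop and leave the reconstructed curve
strictly positive.

**Patient records.** Events are emitted at their drop times, censorings at
their spread times, and patients still at risk after the last coordinate
as censored at the last time, so the row count equals `nrisk_1` exactly
and `Σd + Σc + n_final = nrisk_1` holds by construction (asserted
internally).

Rounding convention everywhere: half away from zero, fixed for
reproducibility.

## Accuracy assessment

The reconstruction's K-M curve is evaluated at every read-in time;
residual summaries are the RMSE, mean and max absolute error, with
advisory thresholds 0.05 / 0.02 / 0.05 surfaced as warnings, never errors.
A drop digitized as top and bottom points shares one time value, so the
step function is evaluated at the **left limit** for the top point and the
right limit for the bottom — the only well-defined comparison of two step
functions at a discontinuity; a one-sided-only lookup would charge the
entire drop height as error at every top point. The distributional check
is a two-sample Kolmogorov-Smirnov comparison of the read-in and estimated
survival-value vectors at the same times (the construction is a design
choice; large p-values indicate agreement). Number-at-risk recovery
reports signed per-`trisk` errors of the implied at-risk counts.

## Secondary analysis

Product-limit fitting and event-table bookkeeping go through lifelines;
Greenwood variances `S² Σ d/(n(n−d))` and Nelson-Aalen increments `d/n`
are computed on the spec'd formulas and cross-checked against hand-derived
values in the tests. Landmark survival confidence intervals use the
log(−log) transform so bounds stay inside [0, 1]. Quantile times are the
smallest event time with `S ≤ s` (right-continuous crossing). Hazard
ratios come from the Cox partial likelihood with Efron tie handling —
material here, because reconstructed data put many events at identical
drop times. The bootstrap interval is percentile-based, stratified by arm
(B = 1000 by default; tests use 120–200 replicates to stay fast).

## Trial simulator

The generator emulates the validation design the package is built around:
200 patients per arm; event times Weibull with survival
`S(t) = exp(−λ t^γ)` and mean survival 12 months (treatment) vs 6 months
(control); uniform accrual over 36 months with 24 further months of
follow-up, administrative censoring on each patient's own clock at
`60 − entry` months; exponential dropout with rate calibrated by
Monte-Carlo bisection (100 000 draws, common random numbers, tolerance
±0.5 percentage points) so the overall censoring fraction hits 30% or
60%; number at risk reported every 3 months (up to 20 reporting times) or
every 10 months (6 times) or not at all. The calibration stream uses a
fixed internal seed and is cached: the dropout rate is a property of the
design, like a protocol constant, while all replicate randomness flows
from the user's seed. The mean-to-scale map uses the standard Weibull mean
`scale · Γ(1 + 1/γ)` with `λ = scale^{−γ}`; the common shape across arms
makes the true hazard ratio `(mean_ctrl/mean_treat)^γ` exact. The design
grid spans γ ∈ {0.5, 1, 1.5} (decreasing, constant, increasing hazard) ×
censoring {30%, 60%}.

Exported coordinates are the *exact* step coordinates of the realized
curve (curve start, top and bottom of every drop, end of the horizontal
tail); `digitization_noise` adds independent Gaussian jitter to emulate
manual extraction. The simulator therefore does **not** emulate:
correlated digitization error along a curve, pixel quantization, tangled
or overlapping curves, informative or covariate-dependent censoring, or
mis-printed risk tables. Passing tests show the estimator inverts the
product-limit mapping faithfully under uniform censoring and realistic
noise; they do not certify extraction quality from an actual image, which
remains the operator's responsibility (the advisory thresholds exist for
exactly that check).

## Problem sizes and numerical notes

Tests and the acceptance script use the design's own sizes — 200 patients
per arm — with 5–10 seeded replicates per scenario, 20 arm reconstructions
for the number-at-risk summary, and the 12 arms of the six-trial grid for
median recovery; the full suite runs in well under a minute. The
iteration cap per interval is 10 000 (the box guarantees termination; the
cap guards degenerate inputs and triggers a warning, returning the best
iterate). Degenerate inputs are surfaced as typed errors: zero survival at
an interval start with later at-risk counts reported, inconsistent risk
tables, fewer drops than `nrisk_1` can support, unreachable censoring
targets (reported with the administrative floor).

## Known limitations

* Uniform censoring within intervals is an assumption, not an estimate;
  trials with batched follow-up visits or informative dropout violate it.
* Without a number-at-risk table, censoring is unidentifiable and the
  single-interval fallback is only as good as the supplied totals.
* The total-events count enters only through the last-interval seeding;
  no global rebalancing pass is attempted.
* Hazard-ratio comparisons against other implementations are approximate
  wherever the tie-handling convention of the comparator is unknown.
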