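# kmipd

Reconstruct individual patient time-to-event data (IPD) from coordinates
digitized off published Kaplan-Meier survival curves, assess how faithful
the reconstruction is, and run secondary survival analyses on the result.

Meta-analysts and trialists frequently need patient-level survival data
that the original publication does not share. What a paper does print — the
K-M curve, the number-at-risk table beneath it, sometimes the total event
count — constrains the underlying data tightly enough that a patient-level
dataset reproducing all of it can be inferred. `kmipd` implements a
box-constrained iterative estimator for that inference, together with the
preprocessing that real digitized coordinates need (outlier fencing,
monotonicity repair, step control) and a trial simulator so the whole
pipeline can be validated against known truth without any external data.

## Method

For a curve partitioned into the reporting intervals of the number-at-risk
table `(trisk_i, nrisk_i)`, the estimator alternates two steps inside each
interval *i*:

1. **Sweep.** Given a censor total `ncensor_i`, spread the censoring times
   evenly over the interval (constant-censoring assumption) and walk the
   digitized coordinates `(T_k, S_k)` computing

       d_k = round( n_k * (1 − S_k / S_last) ),       n_{k+1} = n_k − d_k − c_k,

   where `S_last` is the running product-limit estimate at the last
   coordinate with an event, updated multiplicatively whenever `d_k > 0`.

2. **Adjust.** Compare the estimated number at risk at the start of the
   next interval with the reported `nrisk_{i+1}` and shift `ncensor_i` by
   the signed discrepancy, constrained to the admissible box
   `[0, nrisk_i − nrisk_{i+1}]`.

The box constraint is the essential stabilisation: without it the censor
update can iterate to negative counts on dense risk tables. The final
interval, which has no reported target, is seeded from the average
censoring rate observed so far and — when the total number of events is
known — from the remaining events budget.

Before estimation, raw digitized points are sorted, percent-scaled input is
normalised, extraction blunders are removed with a quartile fence (k = 3)
on successive survival increments, survival is clamped to a running minimum
("force monotonicity"), and each vertical drop is reduced to its top and
bottom point so the drop's event count rounds exactly once.

Downstream, `kmipd.km` provides the product-limit fit with Greenwood
standard errors, Nelson-Aalen cumulative hazard, survival quantiles, the
two-sample log-rank test, Cox proportional-hazards hazard ratios (Efron tie
handling — reconstructed data are heavily tied at drop times) and a
stratified percentile bootstrap for the HR interval.

## Worked example

Simulate a two-arm trial (200 patients/arm, exponential event times with
12- vs 6-month mean survival, 30% censoring, number at risk reported every
3 months), then reconstruct the treatment arm from its exported curve
coordinates:

```bash
kmipd simulate --seed 11 --out sim
kmipd reconstruct --points sim/coords_treatment.csv \
                  --risk-file sim/risk_treatment.csv --arm treat --out rec
```

```
Reconstruction accuracy
  RMSE:            0.0024 (threshold 0.05)
  mean |error|:    0.0019 (threshold 0.02)
  max |error|:     0.0072 (threshold 0.05)
  KS statistic:    0.0078 (p = 1)
  thresholds met:  yes
```

The RMSE / mean / max absolute errors compare the reconstruction's K-M
curve with the read-in survival values at every digitized time; values
within the advisory thresholds (0.05 / 0.02 / 0.05) indicate the extracted
points were captured well enough for secondary analysis, and the large
Kolmogorov-Smirnov p-value shows no detectable distributional discrepancy.
Reconstructing the control arm too and comparing:

```bash
kmipd reconstruct --points sim/coords_control.csv \
                  --risk-file sim/risk_control.csv --arm control --out rec
kmipd survreport --ipd1 rec/ipd_treat.csv --ipd2 rec/ipd_control.csv --out rep
```

```
Log-rank: chi2=40.066, p=2.456e-10
Hazard ratio (arm treat vs control): 0.439 (95% CI 0.338-0.570)
```

The simulated truth for this seed is HR = 0.5; the reconstructed estimate
sits inside its own confidence interval around it.

The same pipeline is available as a library, with sklearn-style estimators
for the two pipeline stages:

```python
from kmipd import KaplanMeierReconstructor

rec = KaplanMeierReconstructor(trisk=[0, 10, 20], nrisk=[213, 122, 78],
                               arm="radio").fit(coords)   # (N, 2) array
rec.ipd_          # DataFrame: time, status, arm
rec.estimates_    # per-coordinate audit counts
rec.score()       # negative RMSE against the read-in curve
```

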