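"""Accuracy assessment of a reconstruction against the digitized coordinates.

The reconstructed patient data should reproduce the published curve: its
product-limit estimate, evaluated at every read-in time, is compared with
the read-in survival values (RMSE / mean / max absolute error, plus a
two-sample Kolmogorov-Smirnov comparison of the two survival-value
vectors), and the implied number at risk is compared with the reported
risk table.  Rule-of-thumb thresholds — RMSE <= 0.05, mean absolute error
<= 0.02, max absolute error <= 0.05 — flag whether the extracted points
were captured well enough for secondary analysis; the flags are advisory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .km import km_fit, ks_survival_comparison, surv_at
from .preprocess import PreprocessedCurve, RiskTable
from .reconstruct import CountEstimates

__all__ = ["AccuracySummary", "accuracy_summary", "nrisk_recovery", "RMSE_THRESHOLD",
           "MEAN_ABS_THRESHOLD", "MAX_ABS_THRESHOLD"]

RMSE_THRESHOLD = 0.05
MEAN_ABS_THRESHOLD = 0.02
MAX_ABS_THRESHOLD = 0.05


@dataclass
class AccuracySummary:
    """Reconstruction-accuracy metrics and advisory pass flags."""

    rmse: float
    mean_abs_err: float
    max_abs_err: float
    ks_stat: float
    ks_p: float
    residuals: pd.DataFrame          # time, read_in, estimated, residual
    nrisk_table: pd.DataFrame | None  # trisk, reported, estimated, error
    pass_flags: dict

    @property
    def passed(self) -> bool:
        return all(self.pass_flags.values())

    def to_dict(self) -> dict:
        out = {
            "rmse": self.rmse,
            "mean_abs_err": self.mean_abs_err,
            "max_abs_err": self.max_abs_err,
            "ks_stat": self.ks_stat,
            "ks_p": self.ks_p,
            "pass_flags": dict(self.pass_flags),
        }
        if self.nrisk_table is not None:
            out["nrisk_comparison"] = self.nrisk_table.to_dict(orient="list")
        return out

    def to_text(self) -> str:
        lines = [
            "Reconstruction accuracy",
            f"  RMSE:            {self.rmse:.4f} (threshold {RMSE_THRESHOLD})",
            f"  mean |error|:    {self.mean_abs_err:.4f} (threshold {MEAN_ABS_THRESHOLD})",
            f"  max |error|:     {self.max_abs_err:.4f} (threshold {MAX_ABS_THRESHOLD})",
            f"  KS statistic:    {self.ks_stat:.4f} (p = {self.ks_p:.4g})",
            f"  thresholds met:  {'yes' if self.passed else 'NO'}",
        ]
        if self.nrisk_table is not None:
            lines.append("  number-at-risk comparison (reported vs estimated):")
            for _, row in self.nrisk_table.iterrows():
                lines.append(
                    f"    t={row['trisk']:g}: {int(row['reported'])} vs "
                    f"{int(row['estimated'])} (error {int(row['error']):+d})"
                )
        return "\n".join(lines)


def accuracy_summary(prep: PreprocessedCurve, ipd: pd.DataFrame) -> AccuracySummary:
    """Compare the reconstruction's K-M curve with the read-in coordinates.

    Residuals are ``S_hat(T_k) - S_k`` at every read-in time.  A digitized
    vertical drop carries two points at one time (its top and bottom); the
    estimated step function is evaluated at the left limit for the top
    point and at the right limit for the bottom, so a discontinuity is
    compared one-sided rather than charging the whole drop height as
    error.  The number-at-risk comparison counts patients with observed
    time at or beyond each reported risk time.
    """
    n_ipd = len(ipd)
    if n_ipd != prep.total_n:
        raise InvalidInputError(
            f"patient table has {n_ipd} rows but the curve reports {prep.total_n} "
            "patients; the pairing looks wrong"
        )
    fit = km_fit(ipd)
    t_read = prep.points.times
    s_read = prep.points.surv
    s_est = np.atleast_1d(surv_at(fit, t_read))
    # top-of-drop points: same time as the next point, higher survival
    top = np.zeros(t_read.size, dtype=bool)
    top[:-1] = (t_read[:-1] == t_read[1:]) & (s_read[:-1] > s_read[1:])
    if top.any():
        idx = np.searchsorted(fit.event_times, t_read[top], side="left")
        s_left = np.concatenate([[1.0], fit.survival])[idx]
        s_est[top] = s_left
    r = s_est - s_read
    rmse = float(np.sqrt(np.mean(r**2)))
    mean_abs = float(np.mean(np.abs(r)))
    max_abs = float(np.max(np.abs(r)))
    ks_stat, ks_p = ks_survival_comparison(prep.points.surv, s_est)

    nrisk_table = None
    if prep.has_risk_table:
        obs = ipd["time"].to_numpy()
        est = np.array([(obs >= tt).sum() for tt in prep.trisk])
        nrisk_table = pd.DataFrame(
            {
                "trisk": prep.trisk,
                "reported": prep.nrisk,
                "estimated": est,
                "error": est - prep.nrisk,
            }
        )

    flags = {
        "rmse": rmse <= RMSE_THRESHOLD,
        "mean_abs_err": mean_abs <= MEAN_ABS_THRESHOLD,
        "max_abs_err": max_abs <= MAX_ABS_THRESHOLD,
    }
    if not all(flags.values()):
        warnings.warn(
            "reconstruction accuracy falls outside the recommended thresholds; "
            "consider re-extracting the coordinates",
            UserWarning,
            stacklevel=2,
        )
    return AccuracySummary(
        rmse=rmse,
        mean_abs_err=mean_abs,
        max_abs_err=max_abs,
        ks_stat=ks_stat,
        ks_p=ks_p,
        residuals=pd.DataFrame(
            {"time": prep.points.times, "read_in": prep.points.surv,
             "estimated": s_est, "residual": r}
        ),
        nrisk_table=nrisk_table,
        pass_flags=flags,
    )


def nrisk_recovery(estimates: CountEstimates, risk: RiskTable) -> pd.DataFrame:
    """Signed per-risk-time error of the reconstruction's at-risk counts.

    Returns a table with columns ``trisk``, ``reported``, ``estimated`` and
    ``error`` (estimated minus reported); the mean absolute error is
    available as ``df['error'].abs().mean()``.
    """
    if len(estimates.nrisk_est) != risk.n_intervals:
        raise InvalidInputError("estimates and risk table cover different intervals")
    return pd.DataFrame(
        {
            "trisk": risk.trisk,
            "reported": risk.nrisk,
            "estimated": estimates.nrisk_est,
            "error": estimates.nrisk_est - risk.nrisk,
        }
    )


def save_comparison_figure(prep: PreprocessedCurve, ipd: pd.DataFrame, path) -> None:
    """Three-panel overlay figure: curves, number at risk, residuals."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summ = accuracy_summary(prep, ipd)
    fit = km_fit(ipd)
    n_panels = 3 if summ.nrisk_table is not None else 2
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 3.2))
    ax = axes[0]
    ax.step(
        np.concatenate([[0], fit.event_times]),
        np.concatenate([[1.0], fit.survival]),
        where="post", label="reconstructed",
    )
    ax.plot(prep.points.times, prep.points.surv, ".", ms=3, label="read-in")
    ax.set_xlabel("time"); ax.set_ylabel("survival"); ax.legend()
    k = 1
    if summ.nrisk_table is not None:
        ax = axes[k]; k += 1
        ax.plot(summ.nrisk_table["trisk"], summ.nrisk_table["reported"], "o-", label="reported")
        ax.plot(summ.nrisk_table["trisk"], summ.nrisk_table["estimated"], "s--", label="estimated")
        ax.set_xlabel("time"); ax.set_ylabel("number at risk"); ax.legend()
    ax = axes[k]
    ax.axhline(0, color="grey", lw=0.5)
    ax.plot(summ.residuals["time"], summ.residuals["residual"], ".", ms=3)
    ax.set_xlabel("time"); ax.set_ylabel("residual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
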