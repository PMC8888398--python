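"""Per-subject and aggregate dermatopharmacokinetic metrics.

From the paired areal drug masses at the end of uptake (Q_up) and after the
clearance delay (Q_cl):

* input flux into viable tissue  J = (Q_up - Q_cl) / dt
* first-order elimination rate   k = -ln(Q_cl / Q_up) / dt
* relative depletion             1 - Q_cl / Q_up

plus percent of applied dose recovered, a single-pass two-sided Grubbs
outlier screen, and t-based 95 % confidence summaries.

k is computed per site pair (same subject and dose) and then averaged across
subjects; the mean of per-subject ratios is not the ratio of means, so
aggregate-level recomputations from mean Q values are provided separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import mg_to_ng

__all__ = [
    "DPKMetrics",
    "SummaryRow",
    "flux",
    "elim_rate",
    "depletion",
    "pct_dose_recovered",
    "grubbs_screen",
    "grubbs_critical_value",
    "summarize",
    "metrics_table",
    "aggregate_table",
]


@dataclass(frozen=True)
class DPKMetrics:
    subject_id: str
    dose_mg_cm2: float
    q_up_ng_cm2: float
    q_cl_ng_cm2: float
    delta_t_h: float
    j_ng_cm2_h: float
    k_per_h: float | None
    depletion_fraction: float | None
    pct_recovered: float


@dataclass(frozen=True)
class SummaryRow:
    n: int
    mean: float
    sd: float
    ci95_half: float | None  # t-based half width; None when n < 2
    outliers_removed: tuple[int, ...] = ()


def flux(q_up: float, q_cl: float, delta_t_h: float) -> float:
    """Average flux from the SC into viable tissue over the clearance delay."""
    if delta_t_h <= 0:
        raise ValueError("delta_t must be > 0")
    j = (q_up - q_cl) / delta_t_h
    if j < 0:
        warnings.warn(f"negative flux ({j:.3g}): Q_cl exceeds Q_up")
    return j


def elim_rate(q_up: float, q_cl: float, delta_t_h: float) -> float | None:
    """First-order elimination rate constant from the two-point Q ratio.

    Returns None (flagged upstream) when either Q is non-positive — a censored
    clearance measurement must not map to an infinite rate.
    """
    if delta_t_h <= 0:
        raise ValueError("delta_t must be > 0")
    if q_up <= 0 or q_cl <= 0:
        return None
    k = -math.log(q_cl / q_up) / delta_t_h
    if k < 0:
        warnings.warn(f"negative elimination rate ({k:.3g}): Q_cl exceeds Q_up")
    return k


def depletion(q_up: float, q_cl: float) -> float | None:
    """Relative depletion 1 - Q_cl/Q_up; None when Q_up is non-positive."""
    if q_up <= 0:
        return None
    return 1.0 - q_cl / q_up


def pct_dose_recovered(
    q_up_ng_cm2: float, dose_mg_cm2: float, drug_fraction: float = 0.00122
) -> float:
    """Percent of the applied drug found in the SC at the end of uptake."""
    if dose_mg_cm2 <= 0 or drug_fraction <= 0:
        raise ValueError("dose and drug_fraction must be > 0")
    applied_ng_cm2 = mg_to_ng(dose_mg_cm2 * drug_fraction)
    return 100.0 * q_up_ng_cm2 / applied_ng_cm2


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha)."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_screen(
    values, alpha: float = 0.05, max_passes: int = 1
) -> tuple[np.ndarray, list[int]]:
    """Two-sided Grubbs outlier screen; at most one removal per pass.

    Returns (kept values, removed indices into the original array).  Samples
    with zero spread are degenerate and pass through unchanged.  Default is a
    single pass.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-d sample with n >= 3")
    keep = np.arange(len(x))
    removed: list[int] = []
    for _ in range(max_passes):
        sub = x[keep]
        n = len(sub)
        if n < 3:
            break
        s = sub.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(sub - sub.mean())
        g = dev.max() / s
        if g > grubbs_critical_value(n, alpha):
            i = int(np.argmax(dev))
            removed.append(int(keep[i]))
            keep = np.delete(keep, i)
        else:
            break
    return x[keep], removed


def summarize(values, outliers_removed: tuple[int, ...] = ()) -> SummaryRow:
    """Arithmetic mean with a Student-t 95 % confidence half-width."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    mean = float(x.mean())
    if n < 2:
        return SummaryRow(n=n, mean=mean, sd=float("nan"), ci95_half=None,
                          outliers_removed=tuple(outliers_removed))
    sd = float(x.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return SummaryRow(n=n, mean=mean, sd=sd, ci95_half=half,
                      outliers_removed=tuple(outliers_removed))


def metrics_table(
    site_q: pd.DataFrame,
    drug_fraction: float = 0.00122,
) -> pd.DataFrame:
    """Pair uptake/clearance sites per (subject, dose) and compute all metrics.

    ``site_q`` needs columns subject_id, dose_mg_cm2, phase, q_ng_cm2 and
    optionally delta_t_h (default 6).  One row per site pair is returned.
    """
    req = {"subject_id", "dose_mg_cm2", "phase", "q_ng_cm2"}
    if not req.issubset(site_q.columns):
        raise ValueError(f"need columns {sorted(req)}")
    rows = []
    for (subj, dose), g in site_q.groupby(["subject_id", "dose_mg_cm2"]):
        up = g[g["phase"] == "uptake"]
        cl = g[g["phase"] == "clearance"]
        if len(up) != 1 or len(cl) != 1:
            raise ValueError(
                f"subject {subj}, dose {dose}: need exactly one uptake and one "
                f"clearance site, got {len(up)}/{len(cl)}"
            )
        q_up = float(up["q_ng_cm2"].iloc[0])
        q_cl = float(cl["q_ng_cm2"].iloc[0])
        dt = float(cl["delta_t_h"].iloc[0]) if "delta_t_h" in cl.columns else 6.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            j = flux(q_up, q_cl, dt)
            k = elim_rate(q_up, q_cl, dt)
        rows.append(
            {
                "subject_id": subj,
                "dose_mg_cm2": float(dose),
                "q_up_ng_cm2": q_up,
                "q_cl_ng_cm2": q_cl,
                "delta_t_h": dt,
                "j_ng_cm2_h": j,
                "k_per_h": np.nan if k is None else k,
                "depletion_fraction": np.nan if depletion(q_up, q_cl) is None
                else depletion(q_up, q_cl),
                "pct_recovered": pct_dose_recovered(q_up, float(dose), drug_fraction),
            }
        )
    return pd.DataFrame(rows)


def aggregate_table(
    metrics: pd.DataFrame,
    grubbs_alpha: float | None = 0.05,
) -> pd.DataFrame:
    """Dose-level summary of Q_up, Q_cl, J and k (means with 95 % CI).

    When ``grubbs_alpha`` is set, each dose x metric sample is screened once
    with Grubbs' test before summarising.
    """
    out = []
    cols = ["q_up_ng_cm2", "q_cl_ng_cm2", "j_ng_cm2_h", "k_per_h"]
    for dose, g in metrics.groupby("dose_mg_cm2"):
        row: dict = {"dose_mg_cm2": float(dose)}
        for col in cols:
            vals = g[col].dropna().to_numpy()
            removed: list[int] = []
            if grubbs_alpha is not None and len(vals) >= 3:
                vals, removed = grubbs_screen(vals, alpha=grubbs_alpha)
            s = summarize(vals, tuple(removed))
            row[f"{col}_n"] = s.n
            row[f"{col}_mean"] = s.mean
            row[f"{col}_sd"] = s.sd
            row[f"{col}_ci95"] = s.ci95_half
            row[f"{col}_outliers"] = len(removed)
        out.append(row)
    return pd.DataFrame(out)
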