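"""Power and sample size for detecting a fractional change in a metric's mean.

Two-sided one-sample t test: with n observations of standard deviation sd,
the power to detect a true mean shift delta is

    power = P(|T'| > t_{1-a/2, n-1}),   T' ~ noncentral t(n-1, ncp),
    ncp = sqrt(n) * delta / sd

evaluated with the noncentral t distribution.  Sample size is the smallest
integer n >= 2 whose power reaches the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PowerSpec", "power_one_sample_t", "n_one_sample_t", "table2"]


@dataclass(frozen=True)
class PowerSpec:
    mean: float
    sd: float
    n: int
    alpha: float = 0.05
    target_power: float = 0.8
    effect_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")


def power_one_sample_t(delta: float, sd: float, n: int, alpha: float = 0.05) -> float:
    """Exact two-sided one-sample t power via the noncentral t distribution."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    df = n - 1
    ncp = math.sqrt(n) * delta / sd
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def n_one_sample_t(
    delta: float, sd: float, alpha: float = 0.05, target_power: float = 0.8
) -> int:
    """Smallest n >= 2 whose one-sample t power reaches ``target_power``.

    Power is strictly increasing in n, so a downward/upward scan from the
    normal-approximation start finds the exact argmin.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(target_power)
    n = max(2, math.ceil(((z_a + z_b) * sd / delta) ** 2))
    while n > 2 and power_one_sample_t(delta, sd, n - 1, alpha) >= target_power:
        n -= 1
    while power_one_sample_t(delta, sd, n, alpha) < target_power:
        n += 1
    return n


def table2(
    summaries: pd.DataFrame,
    effect_fractions: tuple[float, ...] = (0.2, 0.5),
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> pd.DataFrame:
    """Power/sample-size report for each metric x dose x effect fraction.

    ``summaries`` needs columns metric, dose, mean, sd, n.  Rows with n < 2 or
    sd <= 0 are flagged (``ok=False``) and carry no power.  Achieved power is
    reported in percent to one decimal.
    """
    req = {"metric", "dose", "mean", "sd", "n"}
    if not req.issubset(summaries.columns):
        raise ValueError(f"need columns {sorted(req)}")
    rows = []
    for _, s in summaries.iterrows():
        for frac in effect_fractions:
            delta = abs(float(s["mean"])) * frac
            row = {
                "metric": s["metric"],
                "dose": s["dose"],
                "mean": float(s["mean"]),
                "sd": float(s["sd"]),
                "n": int(s["n"]),
                "effect_fraction": frac,
                "delta": delta,
                # half-up integer rounding for display, as in printed reports
                "delta_display": int(math.floor(delta + 0.5)),
                "ok": True,
            }
            if row["n"] < 2 or row["sd"] <= 0 or delta == 0:
                row.update(ok=False, required_n=np.nan, power_pct=np.nan)
            else:
                row["required_n"] = n_one_sample_t(delta, row["sd"], alpha, target_power)
                row["power_pct"] = round(
                    100.0 * power_one_sample_t(delta, row["sd"], row["n"], alpha), 1
                )
            rows.append(row)
    return pd.DataFrame(rows)
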