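"""Skin-blanching normalisation and the area-above-the-effect-curve statistic.

The treated-site colour change on the chromameter a* scale is corrected by the
mean change at three untreated control sites, which cancels any colour drift
common to the arm.  The response summary is the signed trapezoidal integral of
the corrected change over 0-22 h (units: hours, since the a* change is
dimensionless); negative values indicate blanching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BlanchingSeries", "AAECResult", "delta_a", "aaec", "responder_table"]


@dataclass(frozen=True)
class BlanchingSeries:
    """a* readings at one treated site and its 3 controls on a shared time grid."""

    subject_id: str
    site_id: str
    times_h: list[float]
    treated_baseline: float
    treated: list[float]
    control_baselines: list[float]  # controls 1..3
    controls: list[list[float]]  # shape (3, n_times)
    dose_mg_cm2: float | None = None

    def __post_init__(self) -> None:
        if len(self.control_baselines) != 3 or len(self.controls) != 3:
            raise ValueError("exactly 3 control sites are required")
        n = len(self.times_h)
        if len(self.treated) != n or any(len(c) != n for c in self.controls):
            raise ValueError("all roles must share the same time grid")
        if list(self.times_h) != sorted(self.times_h):
            raise ValueError("times must be increasing")


@dataclass(frozen=True)
class AAECResult:
    aaec_h: float
    responder: bool  # aaec < 0
    times_h: tuple[float, ...]
    delta_a: tuple[float, ...]


def delta_a(series: BlanchingSeries) -> np.ndarray:
    """Control-corrected treated-site change at each time point.

    delta = (treated_t - treated_0) - mean_n(control_n,t - control_n,0).
    Uniform drift applied to the treated site and all controls cancels exactly.
    """
    d_treated = np.asarray(series.treated, dtype=float) - series.treated_baseline
    d_controls = np.asarray(series.controls, dtype=float) - np.asarray(
        series.control_baselines, dtype=float
    )[:, None]
    return d_treated - d_controls.mean(axis=0)


def aaec(
    delta: np.ndarray | list[float],
    times_h: np.ndarray | list[float],
    anchor: bool = True,
) -> AAECResult:
    """Signed trapezoidal integral of the corrected change over [0, 22] h.

    With ``anchor`` (default) a zero point at t=0 — the moment the formulation
    is removed, where the normalisation makes the change 0 by construction —
    is prepended so the integral spans the full interval.
    """
    t = np.asarray(times_h, dtype=float)
    d = np.asarray(delta, dtype=float)
    if t.shape != d.shape:
        raise ValueError("times and delta must have the same length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(t <= 0):
        raise ValueError("times must be > 0 (post-removal)")
    if anchor:
        t = np.concatenate([[0.0], t])
        d = np.concatenate([[0.0], d])
    area = float(np.trapezoid(d, t))
    return AAECResult(
        aaec_h=area,
        responder=area < 0,
        times_h=tuple(np.asarray(times_h, dtype=float)),
        delta_a=tuple(np.asarray(delta, dtype=float)),
    )


def responder_table(aaec_by_subject_dose: pd.DataFrame) -> dict:
    """Classify responders per dose and build the power-analysis subsets.

    Parameters
    ----------
    aaec_by_subject_dose
        Columns ``subject_id``, ``dose_mg_cm2``, ``aaec_h``.

    Returns a dict with the wide response matrix (True = responder), per-dose
    responder counts, and the two subject subsets used downstream:
    ``any_dose`` (responded to >= 1 dose) and ``all_doses``.
    """
    req = {"subject_id", "dose_mg_cm2", "aaec_h"}
    if not req.issubset(aaec_by_subject_dose.columns):
        raise ValueError(f"need columns {sorted(req)}")
    wide = aaec_by_subject_dose.pivot_table(
        index="subject_id", columns="dose_mg_cm2", values="aaec_h", aggfunc="mean"
    )
    matrix = wide < 0
    if matrix.isna().any().any():
        warnings.warn("missing subject x dose cells treated as non-response")
        matrix = matrix.fillna(False)
    counts = matrix.sum(axis=0).to_dict()
    any_dose = sorted(matrix.index[matrix.any(axis=1)])
    all_doses = sorted(matrix.index[matrix.all(axis=1)])
    return {
        "matrix": matrix,
        "counts_by_dose": {float(k): int(v) for k, v in counts.items()},
        "any_dose": any_dose,
        "all_doses": all_doses,
    }
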