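"""Synthetic tape-strip + blanching study generator.

Produces complete studies with the statistical structure the analysis layer
assumes, so the whole pipeline can be exercised and power experiments run
without experimental data.

Physical model
--------------
Drug uptake into the SC follows Fickian diffusion through a finite membrane
with the surface held at a constant concentration ``kcv`` (vehicle
concentration times the SC/vehicle partition coefficient) and a perfect sink
at the base.  With x the fractional depth and tau = (D/L^2) * t:

    C(x, t) / kcv = (1 - x) - sum_{n>=1} (2 / n pi) sin(n pi x) exp(-n^2 pi^2 tau)

Clearance after formulation removal is modelled as uniform first-order decay
of the whole profile — exactly the assumption the two-point rate-constant
estimator makes, giving recovery tests an exact ground truth (continued
diffusion during clearance is deliberately out of scope).

Tape stripping removes lognormally distributed SC masses per strip; TEWL
rises with the reciprocal of the remaining SC thickness and stripping stops
on the first rule hit.  Pooled groups are assayed with multiplicative
Gaussian noise and censored below the limit of quantification.

All randomness flows from one seed through deterministic per-subject
substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    AssayConfig,
    ChromameterReading,
    SiteTreatment,
    StoppingRule,
    StripGroup,
    TapeStripRecord,
    group_id_for,
    ug_per_ml_to_ng_per_ml,
)

__all__ = [
    "SubjectParams",
    "SimConfig",
    "ConcentrationProfile",
    "uptake_profile",
    "clearance_profile",
    "strip_site",
    "assay_groups",
    "simulate_blanching",
    "simulate_study",
    "StudyTables",
]

UM_TO_CM = 1e-4
SERIES_RTOL = 1e-12
MAX_SERIES_TERMS = 100_000

#: default chromameter sampling times (h post-removal)
BLANCHING_TIMES = (2.0, 4.0, 6.0, 20.0, 22.0)


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth physiology/chemistry for one subject.

    kcv_ng_cm3        surface SC concentration (partition x vehicle conc)
    d_over_l2_per_h   diffusivity over squared SC thickness
    sc_thickness_um   total SC thickness L
    k_true_per_h      first-order elimination rate during clearance
    strip_mass_mg_cm2 mean SC mass removed per tape, per unit area
    """

    kcv_ng_cm3: float = 3.0e5
    d_over_l2_per_h: float = 0.03
    sc_thickness_um: float = 13.0
    k_true_per_h: float = 0.065
    strip_mass_mg_cm2: float = 0.0245
    responder: bool = True
    blanching_scale: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "kcv_ng_cm3",
            "d_over_l2_per_h",
            "sc_thickness_um",
            "k_true_per_h",
            "strip_mass_mg_cm2",
            "blanching_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Study design + variability knobs; ``seed`` is mandatory."""

    seed: int
    n_subjects: int = 12
    doses_mg_cm2: tuple[float, ...] = (2.0, 5.0, 10.0)
    uptake_h: float = 4.0
    clearance_h: float = 6.0
    area_cm2: float = 5.0
    grouping: tuple[int, ...] = (2, 6, 6, 6)
    subject_cv: float = 0.30  # lognormal CV on kcv, D/L^2, strip mass
    strip_cv: float = 0.15  # strip-to-strip SC mass CV
    analytical_cv: float = 0.10
    responder_prob: float = 0.75
    tewl_baseline: float = 10.0  # g m^-2 h^-1
    #: mild sub-linear dose scaling of the surface concentration
    dose_exponent: float = 0.15
    blanching_noise_sd: float = 0.5
    blanching_q50_ng_cm2: float = 50.0
    base_params: SubjectParams = field(default_factory=SubjectParams)
    assay: AssayConfig = field(default_factory=AssayConfig)
    rule: StoppingRule = field(default_factory=StoppingRule)

    def __post_init__(self) -> None:
        if self.subject_cv < 0 or self.strip_cv < 0 or self.analytical_cv < 0:
            raise ValueError("CVs must be >= 0")
        if not 0 <= self.responder_prob <= 1:
            raise ValueError("responder_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# concentration profiles
# ---------------------------------------------------------------------------


def uptake_profile(
    x, t_h: float, params: SubjectParams, n_terms: int | None = None
):
    """Concentration (ng cm^-3) at fractional depth x after t hours of uptake.

    Truncates the eigenfunction series when a term's magnitude drops below
    1e-12 of the surface concentration; pass ``n_terms`` to force a count.
    """
    if t_h < 0:
        raise ValueError("t must be >= 0")
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    if t_h == 0:
        return np.where(x == 0.0, params.kcv_ng_cm3, 0.0)
    tau = params.d_over_l2_per_h * t_h
    acc = 1.0 - x
    n = 1
    while n <= (n_terms or MAX_SERIES_TERMS):
        amp = 2.0 / (n * math.pi) * math.exp(-(n * math.pi) ** 2 * tau)
        acc = acc - amp * np.sin(n * math.pi * x)
        if n_terms is None and amp < SERIES_RTOL:
            break
        n += 1
    return params.kcv_ng_cm3 * np.clip(acc, 0.0, 1.0)


@dataclass(frozen=True)
class ConcentrationProfile:
    """An uptake profile, optionally scaled by first-order clearance decay."""

    params: SubjectParams
    t_uptake_h: float
    scale: float = 1.0

    def concentration(self, x) -> np.ndarray:
        return self.scale * uptake_profile(x, self.t_uptake_h, self.params)

    def areal_mass(self, x_from: float = 0.0, x_to: float = 1.0) -> float:
        """Drug per unit area (ng cm^-2) in the depth slab [x_from, x_to].

        Uses the exact antiderivative of the series, so slab masses are
        consistent with the pointwise concentrations to machine precision.
        """
        if not 0.0 <= x_from <= x_to <= 1.0:
            raise ValueError("need 0 <= x_from <= x_to <= 1")
        if self.t_uptake_h == 0:
            return 0.0
        tau = self.params.d_over_l2_per_h * self.t_uptake_h

        def antideriv(x: float) -> float:
            val = x - x * x / 2.0
            n = 1
            while n <= MAX_SERIES_TERMS:
                amp = 2.0 / (n * math.pi) ** 2 * math.exp(-(n * math.pi) ** 2 * tau)
                val += amp * math.cos(n * math.pi * x)
                if amp < SERIES_RTOL:
                    break
                n += 1
            return val

        integral = antideriv(x_to) - antideriv(x_from)
        l_cm = self.params.sc_thickness_um * UM_TO_CM
        return self.scale * self.params.kcv_ng_cm3 * l_cm * max(integral, 0.0)


def clearance_profile(
    profile: ConcentrationProfile, elapsed_h: float, k_true_per_h: float
) -> ConcentrationProfile:
    """Scale the whole profile by exp(-k * elapsed): uniform first-order decay."""
    if elapsed_h < 0:
        raise ValueError("elapsed must be >= 0")
    return replace(profile, scale=profile.scale * math.exp(-k_true_per_h * elapsed_h))


# ---------------------------------------------------------------------------
# tape stripping and assay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrippedSite:
    records: tuple[TapeStripRecord, ...]
    drug_ng: tuple[float, ...]  # true drug mass per strip, pre-assay
    tewl_trace: tuple[float, ...]  # after each strip
    stop_reason: str  # "tewl_abs" | "tewl_fold" | "max_strips" | "sc_exhausted"


def strip_site(
    profile: ConcentrationProfile,
    params: SubjectParams,
    rule: StoppingRule,
    rng: np.random.Generator,
    subject_id: str,
    site_id: str,
    area_cm2: float = 5.0,
    strip_cv: float = 0.30,
    tewl_baseline: float = 10.0,
    density_g_cm3: float = 1.0,
) -> StrippedSite:
    """Tape-strip a site until the first stopping rule fires.

    Per-strip SC mass is lognormal around the subject mean; cumulative removal
    is capped at the full SC.  TEWL after removing depth h follows the inverse
    remaining-thickness law TEWL0 * L / (L - h).  The drug on each strip is the
    slab integral of the concentration profile over the removed depths.
    """
    L = params.sc_thickness_um
    mean_mass = params.strip_mass_mg_cm2 * area_cm2
    if strip_cv > 0:
        sigma = math.sqrt(math.log(1.0 + strip_cv**2))
        mu = math.log(mean_mass) - sigma**2 / 2.0
    records: list[TapeStripRecord] = []
    drug: list[float] = []
    tewl_trace: list[float] = []
    depth = 0.0  # um removed so far
    stop_reason = "max_strips"
    for i in range(1, rule.max_strips + 1):
        mass = mean_mass if strip_cv == 0 else float(rng.lognormal(mu, sigma))
        thickness = 10.0 * mass / (area_cm2 * density_g_cm3)  # um
        if depth + thickness >= L:  # cap at full SC
            thickness = L - depth
            mass = thickness * area_cm2 * density_g_cm3 / 10.0
        x1, x2 = depth / L, (depth + thickness) / L
        drug.append(profile.areal_mass(x1, x2) * area_cm2)
        depth += thickness
        records.append(
            TapeStripRecord(
                subject_id=subject_id,
                site_id=site_id,
                strip_index=i,
                sc_mass_mg=mass,
                area_cm2=area_cm2,
            )
        )
        remaining = L - depth
        tewl = math.inf if remaining <= 0 else tewl_baseline * L / remaining
        tewl_trace.append(tewl)
        if remaining <= 0:
            stop_reason = "sc_exhausted"
            break
        if tewl >= rule.tewl_abs_max:
            stop_reason = "tewl_abs"
            break
        if tewl >= rule.tewl_fold_max * tewl_baseline:
            stop_reason = "tewl_fold"
            break
    return StrippedSite(
        records=tuple(records),
        drug_ng=tuple(drug),
        tewl_trace=tuple(tewl_trace),
        stop_reason=stop_reason,
    )


def assay_groups(
    site: StrippedSite,
    grouping: tuple[int, ...] = (2, 6, 6, 6),
    assay: AssayConfig = AssayConfig(),
    rng: np.random.Generator | None = None,
    analytical_cv: float = 0.10,
) -> list[StripGroup]:
    """Pool strips per the grouping scheme and apply the assay model.

    Group drug mass is the true pooled mass times (1 + Gaussian noise at the
    analytical CV), floored at zero; groups whose extract concentration falls
    below the LOQ are flagged BLQ and carry no number.  A grouping that
    exceeds the available strips truncates its last group.
    """
    n = len(site.records)
    loq_ng = ug_per_ml_to_ng_per_ml(assay.loq_ug_ml) * assay.extraction_volume_ml
    groups: list[StripGroup] = []
    start = 0
    for size in grouping:
        if start >= n:
            break
        members = list(range(start + 1, min(start + size, n) + 1))
        start += len(members)
        true_mass = sum(site.drug_ng[i - 1] for i in members)
        if analytical_cv > 0 and rng is not None:
            measured = true_mass * (1.0 + analytical_cv * float(rng.standard_normal()))
        else:
            measured = true_mass
        measured = max(measured, 0.0)
        blq = measured < loq_ng
        groups.append(
            StripGroup(
                subject_id=site.records[0].subject_id,
                site_id=site.records[0].site_id,
                group_id=group_id_for(members),
                strip_indices=tuple(members),
                sc_mass_total_mg=sum(
                    site.records[i - 1].sc_mass_mg for i in members
                ),
                drug_mass_ng=None if blq else measured,
                blq=blq,
                extraction_volume_ml=assay.extraction_volume_ml,
            )
        )
    # leftover strips beyond the grouping scheme form one trailing group
    if start < n:
        members = list(range(start + 1, n + 1))
        true_mass = sum(site.drug_ng[i - 1] for i in members)
        if analytical_cv > 0 and rng is not None:
            measured = true_mass * (1.0 + analytical_cv * float(rng.standard_normal()))
        else:
            measured = true_mass
        measured = max(measured, 0.0)
        blq = measured < loq_ng
        groups.append(
            StripGroup(
                subject_id=site.records[0].subject_id,
                site_id=site.records[0].site_id,
                group_id=group_id_for(members),
                strip_indices=tuple(members),
                sc_mass_total_mg=sum(site.records[i - 1].sc_mass_mg for i in members),
                drug_mass_ng=None if blq else measured,
                blq=blq,
                extraction_volume_ml=assay.extraction_volume_ml,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# blanching simulation
# ---------------------------------------------------------------------------


def blanching_template(t_h, peak_h: float = 6.0) -> np.ndarray:
    """Unit-peak response shape: rises to 1 at ``peak_h`` and decays after."""
    t = np.asarray(t_h, dtype=float)
    return (t / peak_h) * np.exp(1.0 - t / peak_h)


def emax_link(q_ng_cm2: float, q50_ng_cm2: float = 50.0) -> float:
    """Saturating link from delivered drug to response amplitude, in [0, 1)."""
    if q_ng_cm2 <= 0:
        return 0.0
    return q_ng_cm2 / (q_ng_cm2 + q50_ng_cm2)


def simulate_blanching(
    subject_id: str,
    site_id: str,
    q_delivered_ng_cm2: float,
    params: SubjectParams,
    rng: np.random.Generator,
    times_h: tuple[float, ...] = BLANCHING_TIMES,
    noise_sd: float = 0.5,
    q50_ng_cm2: float = 50.0,
    drift_sd: float = 1.0,
) -> list[ChromameterReading]:
    """Simulate a* readings at one treated site and its three controls.

    The treated site carries the systematic blanching component
    ``-scale * emax(Q) * template(t)`` (zero for non-responders); a common
    drift term is shared by all four sites so it cancels under normalisation;
    i.i.d. measurement noise is added everywhere.
    """
    times = tuple(float(t) for t in times_h)
    baselines = {"treated": float(rng.normal(10.0, 1.0))}
    for c in ("control1", "control2", "control3"):
        baselines[c] = float(rng.normal(10.0, 1.0))
    drift = drift_sd * rng.standard_normal(len(times))
    amp = (
        params.blanching_scale * emax_link(q_delivered_ng_cm2, q50_ng_cm2)
        if params.responder
        else 0.0
    )
    systematic = -amp * blanching_template(np.array(times))

    readings: list[ChromameterReading] = []
    for role in ("treated", "control1", "control2", "control3"):
        readings.append(
            ChromameterReading(subject_id, site_id, role, None, baselines[role])
        )
        for j, t in enumerate(times):
            val = baselines[role] + drift[j]
            if role == "treated":
                val += float(systematic[j])
            if noise_sd > 0:
                val += noise_sd * float(rng.standard_normal())
            readings.append(ChromameterReading(subject_id, site_id, role, t, val))
    return readings


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyTables:
    records: list[TapeStripRecord]
    groups: list[StripGroup]
    treatments: list[SiteTreatment]
    readings: list[ChromameterReading]
    ground_truth: pd.DataFrame  # per site: k_true, q_true, removed depth
    dose_by_sb_site: dict


def _draw_subject(cfg: SimConfig, rng: np.random.Generator) -> SubjectParams:
    base = cfg.base_params

    def ln(mean: float) -> float:
        if cfg.subject_cv == 0:
            return mean
        sigma = math.sqrt(math.log(1.0 + cfg.subject_cv**2))
        return float(rng.lognormal(math.log(mean) - sigma**2 / 2.0, sigma))

    L = float(np.clip(rng.normal(base.sc_thickness_um, 2.5), 8.0, 20.0))
    return SubjectParams(
        kcv_ng_cm3=ln(base.kcv_ng_cm3),
        d_over_l2_per_h=ln(base.d_over_l2_per_h),
        sc_thickness_um=L,
        k_true_per_h=ln(base.k_true_per_h),
        strip_mass_mg_cm2=ln(base.strip_mass_mg_cm2),
        responder=bool(rng.random() < cfg.responder_prob),
        blanching_scale=ln(base.blanching_scale),
    )


def simulate_study(cfg: SimConfig) -> StudyTables:
    """Generate the full study: per subject, one uptake + one clearance
    tape-strip site and one blanching site per dose.  Deterministic given
    ``cfg.seed``; subjects use independent substreams spawned from the seed.
    """
    root = np.random.SeedSequence(cfg.seed)
    subject_seeds = root.spawn(cfg.n_subjects)
    rule = cfg.rule
    assay = cfg.assay

    records: list[TapeStripRecord] = []
    groups: list[StripGroup] = []
    treatments: list[SiteTreatment] = []
    readings: list[ChromameterReading] = []
    truth_rows: list[dict] = []
    dose_by_sb_site: dict = {}

    for s in range(cfg.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        subj = f"S{s + 1:02d}"
        params = _draw_subject(cfg, rng)
        for dose in cfg.doses_mg_cm2:
            # surface concentration scales mildly, sub-linearly with dose
            dose_scale = (dose / 5.0) ** cfg.dose_exponent
            p_dose = replace(params, kcv_ng_cm3=params.kcv_ng_cm3 * dose_scale)
            up_profile = ConcentrationProfile(p_dose, cfg.uptake_h)
            cl_profile = clearance_profile(up_profile, cfg.clearance_h, params.k_true_per_h)
            for phase, profile in (("uptake", up_profile), ("clearance", cl_profile)):
                site_id = f"{subj}-d{dose:g}-{phase[:2]}"
                stripped = strip_site(
                    profile,
                    p_dose,
                    rule,
                    rng,
                    subject_id=subj,
                    site_id=site_id,
                    area_cm2=cfg.area_cm2,
                    strip_cv=cfg.strip_cv,
                    tewl_baseline=cfg.tewl_baseline,
                    density_g_cm3=assay.sc_density_g_cm3,
                )
                site_groups = assay_groups(
                    stripped, cfg.grouping, assay, rng, cfg.analytical_cv
                )
                records.extend(stripped.records)
                groups.extend(site_groups)
                treatments.append(
                    SiteTreatment(
                        subject_id=subj,
                        site_id=site_id,
                        dose_mg_cm2=dose,
                        phase=phase,
                        uptake_duration_h=cfg.uptake_h,
                        clearance_delay_h=cfg.clearance_h,
                    )
                )
                removed_um = sum(
                    10.0 * r.sc_mass_mg / (cfg.area_cm2 * assay.sc_density_g_cm3)
                    for r in stripped.records
                )
                truth_rows.append(
                    {
                        "subject_id": subj,
                        "site_id": site_id,
                        "dose_mg_cm2": dose,
                        "phase": phase,
                        "k_true_per_h": params.k_true_per_h,
                        "q_true_full_ng_cm2": profile.areal_mass(0.0, 1.0),
                        "q_true_removed_ng_cm2": sum(stripped.drug_ng) / cfg.area_cm2,
                        "removed_um": removed_um,
                        "n_strips": len(stripped.records),
                        "stop_reason": stripped.stop_reason,
                    }
                )
            # blanching driven by the drug delivered out of the SC
            sb_site = f"{subj}-d{dose:g}-sb"
            q_up = up_profile.areal_mass(0.0, 1.0)
            readings.extend(
                simulate_blanching(
                    subj,
                    sb_site,
                    q_up,
                    params,
                    rng,
                    times_h=BLANCHING_TIMES,
                    noise_sd=cfg.blanching_noise_sd,
                    q50_ng_cm2=cfg.blanching_q50_ng_cm2,
                )
            )
            dose_by_sb_site[(subj, sb_site)] = dose

    return StudyTables(
        records=records,
        groups=groups,
        treatments=treatments,
        readings=readings,
        ground_truth=pd.DataFrame(truth_rows),
        dose_by_sb_site=dose_by_sb_site,
    )
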