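"""Domain types and delimited-text readers/writers shared by all pipeline stages.

Canonical units are fixed per field and never mixed: SC mass in mg, drug mass
in ng, area in cm**2, volume in mL, concentration limits in ug/mL, time in
hours, TEWL in g m**-2 h**-1.  Conversion helpers live here so the factor of
10**6 between mg and ng (and the ug/mL <-> ng/mL factor of 10**3) appears in
exactly one place.

Tape-strip studies are two-level: individual tapes carry SC mass, while drug
is assayed on pooled groups of tapes.  Both levels are stored in one long CSV
(one row per tape, one row per assayed group) so the file is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TapeStripRecord",
    "StripGroup",
    "SiteTreatment",
    "AssayConfig",
    "ChromameterReading",
    "StoppingRule",
    "TableFormatError",
    "read_strip_table",
    "write_strip_table",
    "read_chromameter_table",
    "write_chromameter_table",
    "mg_to_ng",
    "ng_to_mg",
    "ug_per_ml_to_ng_per_ml",
]

#: mg -> ng
MG_TO_NG = 1e6
#: ug/mL -> ng/mL
UG_ML_TO_NG_ML = 1e3

BASELINE_SENTINEL = "pre"

STRIP_TABLE_COLUMNS = [
    "subject_id",
    "site_id",
    "strip_index",
    "sc_mass_mg",
    "area_cm2",
    "group_id",
    "drug_mass_ng",
    "blq_flag",
    "extraction_volume_ml",
]

CHROMAMETER_COLUMNS = ["subject_id", "site_id", "role", "time_h", "a_star", "replicate"]

CONTROL_ROLES = ("control1", "control2", "control3")


def mg_to_ng(mass_mg: float) -> float:
    return mass_mg * MG_TO_NG


def ng_to_mg(mass_ng: float) -> float:
    return mass_ng / MG_TO_NG


def ug_per_ml_to_ng_per_ml(conc_ug_ml: float) -> float:
    return conc_ug_ml * UG_ML_TO_NG_ML


class TableFormatError(ValueError):
    """Raised when an input table violates the schema; carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


@dataclass(frozen=True)
class TapeStripRecord:
    """One removed tape: its SC mass and the area it sampled."""

    subject_id: str
    site_id: str
    strip_index: int
    sc_mass_mg: float
    area_cm2: float

    def __post_init__(self) -> None:
        if self.strip_index < 1:
            raise ValueError(f"strip_index must be >= 1, got {self.strip_index}")
        if self.sc_mass_mg < 0:
            raise ValueError(f"sc_mass_mg must be >= 0, got {self.sc_mass_mg}")
        if self.area_cm2 <= 0:
            raise ValueError(f"area_cm2 must be > 0, got {self.area_cm2}")


@dataclass(frozen=True)
class StripGroup:
    """Pooled tapes sharing one assayed drug mass — the unit carrying concentration.

    ``drug_mass_ng`` is ``None`` when the assay was below the limit of
    quantification (``blq=True``); censoring is preserved, never encoded as 0.
    """

    subject_id: str
    site_id: str
    group_id: str
    strip_indices: tuple[int, ...]
    sc_mass_total_mg: float
    drug_mass_ng: float | None
    blq: bool = False
    extraction_volume_ml: float = 2.0

    def __post_init__(self) -> None:
        idx = tuple(self.strip_indices)
        if not idx:
            raise ValueError("strip_indices must be non-empty")
        if list(idx) != list(range(idx[0], idx[0] + len(idx))):
            raise ValueError(f"strip_indices must be contiguous, got {idx}")
        if self.blq:
            if self.drug_mass_ng is not None:
                raise ValueError("BLQ group must not carry a numeric drug mass")
        else:
            if self.drug_mass_ng is None or self.drug_mass_ng < 0:
                raise ValueError("non-BLQ group needs drug_mass_ng >= 0")
        if self.sc_mass_total_mg < 0:
            raise ValueError("sc_mass_total_mg must be >= 0")
        if self.extraction_volume_ml <= 0:
            raise ValueError("extraction_volume_ml must be > 0")


@dataclass(frozen=True)
class SiteTreatment:
    """Dosing metadata for one treated site."""

    subject_id: str
    site_id: str
    dose_mg_cm2: float
    phase: str  # "uptake" | "clearance"
    uptake_duration_h: float = 4.0
    clearance_delay_h: float = 6.0
    drug_fraction: float = 0.00122  # 0.122 % w/w

    def __post_init__(self) -> None:
        if self.phase not in ("uptake", "clearance"):
            raise ValueError(f"phase must be uptake|clearance, got {self.phase!r}")
        if self.dose_mg_cm2 <= 0:
            raise ValueError("dose must be > 0")
        if self.phase == "clearance" and self.clearance_delay_h <= 0:
            raise ValueError("clearance_delay_h must be > 0 for clearance sites")


@dataclass(frozen=True)
class AssayConfig:
    """Extraction/quantification parameters and the SC density assumption."""

    loq_ug_ml: float = 0.032
    lod_ug_ml: float = 0.01
    extraction_volume_ml: float = 2.0
    sc_density_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        if not self.lod_ug_ml < self.loq_ug_ml:
            raise ValueError("lod must be < loq")
        if self.sc_density_g_cm3 <= 0:
            raise ValueError("sc_density must be > 0")
        if self.extraction_volume_ml <= 0:
            raise ValueError("extraction_volume must be > 0")


@dataclass(frozen=True)
class ChromameterReading:
    """One averaged a* reading at a site/role/time."""

    subject_id: str
    site_id: str
    role: str  # treated | control1 | control2 | control3
    time_h: float | None  # None = pre-application baseline
    a_star: float

    def __post_init__(self) -> None:
        if self.role != "treated" and self.role not in CONTROL_ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class StoppingRule:
    """Tape-stripping termination thresholds."""

    tewl_abs_max: float = 60.0  # g m^-2 h^-1
    tewl_fold_max: float = 6.0
    max_strips: int = 20

    def __post_init__(self) -> None:
        if self.max_strips < 1:
            raise ValueError("max_strips must be >= 1")


# ---------------------------------------------------------------------------
# strip table IO
# ---------------------------------------------------------------------------


def write_strip_table(
    records: Iterable[TapeStripRecord],
    groups: Iterable[StripGroup],
    path: str | Path,
) -> None:
    """Write tapes and assayed groups to one long CSV (schema STRIP_TABLE_COLUMNS).

    Tape rows have a strip_index and empty drug columns; group rows have an
    empty strip_index and carry the assay result.  BLQ is an empty drug mass
    plus blq_flag=1, never a 0 in the file.
    """
    rows: list[dict] = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "site_id": r.site_id,
                "strip_index": r.strip_index,
                "sc_mass_mg": repr(float(r.sc_mass_mg)),
                "area_cm2": repr(float(r.area_cm2)),
                "group_id": "",
                "drug_mass_ng": "",
                "blq_flag": "",
                "extraction_volume_ml": "",
            }
        )
    for g in groups:
        rows.append(
            {
                "subject_id": g.subject_id,
                "site_id": g.site_id,
                "strip_index": "",
                "sc_mass_mg": repr(float(g.sc_mass_total_mg)),
                "area_cm2": "",
                "group_id": g.group_id,
                "drug_mass_ng": "" if g.blq else repr(float(g.drug_mass_ng)),
                "blq_flag": 1 if g.blq else 0,
                "extraction_volume_ml": repr(float(g.extraction_volume_ml)),
            }
        )
    pd.DataFrame(rows, columns=STRIP_TABLE_COLUMNS).to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")


def read_strip_table(
    path: str | Path,
) -> tuple[list[TapeStripRecord], list[StripGroup]]:
    """Read a strip table CSV; validate invariants; return (records, groups).

    Raises :class:`TableFormatError` naming the offending 1-based data row for
    schema violations (negative masses, non-consecutive strip indices, group
    membership referring to unknown strips...).
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "site_id": str, "group_id": str},
        float_precision="round_trip",
    )
    _require_columns(df, STRIP_TABLE_COLUMNS[:-1], path)
    if "extraction_volume_ml" not in df.columns:
        df["extraction_volume_ml"] = float("nan")

    records: list[TapeStripRecord] = []
    group_rows: list[tuple[int, pd.Series]] = []
    for i, row in df.iterrows():
        rownum = int(i) + 1
        if pd.notna(row["strip_index"]):
            try:
                records.append(
                    TapeStripRecord(
                        subject_id=str(row["subject_id"]),
                        site_id=str(row["site_id"]),
                        strip_index=int(row["strip_index"]),
                        sc_mass_mg=float(row["sc_mass_mg"]),
                        area_cm2=float(row["area_cm2"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise TableFormatError(str(exc), row=rownum) from exc
        else:
            group_rows.append((rownum, row))

    # strip indices must be consecutive from 1 within each site
    by_site: dict[tuple[str, str], list[int]] = {}
    for r in records:
        by_site.setdefault((r.subject_id, r.site_id), []).append(r.strip_index)
    for (subj, site), idx in by_site.items():
        if sorted(idx) != list(range(1, len(idx) + 1)):
            raise TableFormatError(
                f"site {site} (subject {subj}): strip indices not consecutive "
                f"from 1: {sorted(idx)}"
            )

    site_records: dict[tuple[str, str], dict[int, TapeStripRecord]] = {}
    for r in records:
        site_records.setdefault((r.subject_id, r.site_id), {})[r.strip_index] = r

    groups: list[StripGroup] = []
    seen_members: dict[tuple[str, str], set[int]] = {}
    for rownum, row in group_rows:
        key = (str(row["subject_id"]), str(row["site_id"]))
        if pd.isna(row["group_id"]) or str(row["group_id"]) == "":
            raise TableFormatError("row has neither strip_index nor group_id", row=rownum)
        blq = bool(pd.notna(row["blq_flag"]) and int(row["blq_flag"]) == 1)
        drug = None if blq else float(row["drug_mass_ng"])
        if not blq and pd.isna(row["drug_mass_ng"]):
            raise TableFormatError("non-BLQ group row lacks drug_mass_ng", row=rownum)
        vol = row["extraction_volume_ml"]
        members = _group_members(key, str(row["group_id"]), site_records, seen_members)
        total = float(row["sc_mass_mg"])
        member_total = sum(site_records[key][i].sc_mass_mg for i in members)
        if abs(total - member_total) > 1e-9 * max(1.0, member_total):
            raise TableFormatError(
                f"group sc_mass {total} != sum of member tapes {member_total}",
                row=rownum,
            )
        try:
            groups.append(
                StripGroup(
                    subject_id=key[0],
                    site_id=key[1],
                    group_id=str(row["group_id"]),
                    strip_indices=members,
                    sc_mass_total_mg=total,
                    drug_mass_ng=drug,
                    blq=blq,
                    extraction_volume_ml=2.0 if pd.isna(vol) else float(vol),
                )
            )
        except ValueError as exc:
            raise TableFormatError(str(exc), row=rownum) from exc
    return records, groups


def _group_members(
    key: tuple[str, str],
    group_id: str,
    site_records: dict[tuple[str, str], dict[int, TapeStripRecord]],
    seen: dict[tuple[str, str], set[int]],
) -> tuple[int, ...]:
    """Group ids encode membership as 'g<first>-<last>' (1-based, inclusive)."""
    if key not in site_records:
        raise TableFormatError(f"group for unknown site {key}")
    try:
        lo, hi = group_id.lstrip("g").split("-")
        members = tuple(range(int(lo), int(hi) + 1))
    except ValueError as exc:
        raise TableFormatError(
            f"group_id must look like 'g<first>-<last>', got {group_id!r}"
        ) from exc
    missing = [i for i in members if i not in site_records[key]]
    if missing:
        raise TableFormatError(f"group {group_id} references missing strips {missing}")
    used = seen.setdefault(key, set())
    overlap = used.intersection(members)
    if overlap:
        raise TableFormatError(f"strips {sorted(overlap)} assigned to two groups")
    used.update(members)
    return members


def group_id_for(strip_indices: Sequence[int]) -> str:
    return f"g{min(strip_indices)}-{max(strip_indices)}"


# ---------------------------------------------------------------------------
# chromameter table IO
# ---------------------------------------------------------------------------


def write_chromameter_table(
    readings: Iterable[ChromameterReading],
    path: str | Path,
    dose_by_site: dict[tuple[str, str], float] | None = None,
) -> None:
    """One row per (already averaged) reading; replicate column kept for schema
    compatibility and set to 1.  Baseline rows carry the 'pre' sentinel time."""
    rows = []
    for r in readings:
        row = {
            "subject_id": r.subject_id,
            "site_id": r.site_id,
            "role": r.role,
            "time_h": BASELINE_SENTINEL if r.time_h is None else repr(float(r.time_h)),
            "a_star": repr(float(r.a_star)),
            "replicate": 1,
        }
        if dose_by_site is not None:
            row["dose_mg_cm2"] = dose_by_site.get((r.subject_id, r.site_id), "")
        rows.append(row)
    cols = CHROMAMETER_COLUMNS + (["dose_mg_cm2"] if dose_by_site is not None else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_chromameter_table(path: str | Path):
    """Read chromameter CSV into :class:`~scdpk.blanching.BlanchingSeries` objects.

    Duplicate replicates at one (site, role, time) are averaged on ingest.
    Every role needs a baseline ('pre') row; each treated site needs all three
    control roles on the same time grid.  An optional dose_mg_cm2 column is
    attached to the returned series when present.
    """
    from .blanching import BlanchingSeries  # deferred: avoids import cycle

    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "site_id": str, "role": str},
        float_precision="round_trip",
    )
    _require_columns(df, CHROMAMETER_COLUMNS, path)
    bad_role = df.loc[~df["role"].isin(("treated",) + CONTROL_ROLES)]
    if len(bad_role):
        raise TableFormatError(
            f"unknown role {bad_role.iloc[0]['role']!r}", row=int(bad_role.index[0]) + 1
        )

    df = (
        df.groupby(["subject_id", "site_id", "role", "time_h"], as_index=False)
        .agg(a_star=("a_star", "mean"), **(
            {"dose_mg_cm2": ("dose_mg_cm2", "first")} if "dose_mg_cm2" in df.columns else {}
        ))
    )

    series: list[BlanchingSeries] = []
    for (subj, site), g in df.groupby(["subject_id", "site_id"]):
        roles = set(g["role"])
        missing = [r for r in ("treated",) + CONTROL_ROLES if r not in roles]
        if missing:
            raise TableFormatError(
                f"site {site} (subject {subj}): missing role(s) {missing}"
            )
        baselines: dict[str, float] = {}
        timed: dict[str, dict[float, float]] = {r: {} for r in roles}
        for _, row in g.iterrows():
            t = str(row["time_h"])
            if t == BASELINE_SENTINEL:
                baselines[row["role"]] = float(row["a_star"])
            else:
                timed[row["role"]][float(t)] = float(row["a_star"])
        for role in ("treated",) + CONTROL_ROLES:
            if role not in baselines:
                raise TableFormatError(
                    f"site {site} (subject {subj}): role {role} lacks a baseline row"
                )
        grids = {role: tuple(sorted(timed[role])) for role in timed}
        if len(set(grids.values())) != 1:
            raise TableFormatError(
                f"site {site} (subject {subj}): roles measured on different time grids"
            )
        times = list(grids["treated"])
        dose = None
        if "dose_mg_cm2" in g.columns:
            vals = pd.to_numeric(g["dose_mg_cm2"], errors="coerce").dropna()
            if len(vals):
                dose = float(vals.iloc[0])
        series.append(
            BlanchingSeries(
                subject_id=str(subj),
                site_id=str(site),
                times_h=times,
                treated_baseline=baselines["treated"],
                treated=[timed["treated"][t] for t in times],
                control_baselines=[baselines[r] for r in CONTROL_ROLES],
                controls=[[timed[r][t] for t in times] for r in CONTROL_ROLES],
                dose_mg_cm2=dose,
            )
        )
    return series
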