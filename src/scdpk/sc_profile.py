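"""Depth profiles and per-site drug totals from tape-strip records.

Depth is measured from the post-cleaning SC surface (0 at the surface) and is
obtained by converting each tape's SC mass per sampled area to a thickness at
the assumed density.  Each assayed group of tapes occupies a contiguous,
half-open depth slab [top, bottom); its average concentration is plotted at
the slab midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    AssayConfig,
    StripGroup,
    TapeStripRecord,
    mg_to_ng,
    ug_per_ml_to_ng_per_ml,
)

__all__ = [
    "DepthProfile",
    "thickness_from_mass",
    "group_concentration",
    "site_Q",
    "build_profile",
    "AllCensoredWarning",
]

BLQ_POLICIES = ("zero", "half-loq")


class AllCensoredWarning(UserWarning):
    """Every group at a site was below the limit of quantification."""


def thickness_from_mass(sc_mass_mg: float, area_cm2: float, density_g_cm3: float = 1.0) -> float:
    """SC thickness (um) removed by a tape: mass / (area * density).

    1 mg over 1 cm**2 at 1 g cm**-3 is a 10-um layer.
    """
    if area_cm2 <= 0:
        raise ValueError("area must be > 0")
    if density_g_cm3 <= 0:
        raise ValueError("density must be > 0")
    return 10.0 * sc_mass_mg / (area_cm2 * density_g_cm3)


def _blq_mass_ng(group: StripGroup, assay: AssayConfig, policy: str) -> float:
    if policy == "zero":
        return 0.0
    if policy == "half-loq":
        # LOQ/2 concentration over the extraction volume
        return ug_per_ml_to_ng_per_ml(assay.loq_ug_ml / 2.0) * group.extraction_volume_ml
    raise ValueError(f"unknown BLQ policy {policy!r}; choose from {BLQ_POLICIES}")


def group_concentration(
    group: StripGroup,
    assay: AssayConfig = AssayConfig(),
    blq_policy: str = "zero",
) -> tuple[float, bool]:
    """Average drug concentration in a group's SC (ng per mg SC), with BLQ flag.

    BLQ groups return the policy value (0 by default) and ``censored=True``.
    """
    if group.blq:
        mass = _blq_mass_ng(group, assay, blq_policy)
    else:
        mass = group.drug_mass_ng
    if group.sc_mass_total_mg <= 0:
        if mass > 0:
            raise ValueError("zero SC mass with nonzero drug")
        return 0.0, group.blq
    return mass / group.sc_mass_total_mg, group.blq


def site_Q(
    groups: list[StripGroup],
    area_cm2: float,
    assay: AssayConfig = AssayConfig(),
    blq_policy: str = "zero",
) -> tuple[float, float]:
    """Total drug per unit area at a site (ng cm**-2) and the censored fraction.

    Q = sum of group drug masses / area; BLQ groups contribute per policy.
    """
    if not groups:
        raise ValueError("need at least one group")
    if area_cm2 <= 0:
        raise ValueError("area must be > 0")
    total = 0.0
    n_blq = 0
    for g in groups:
        if g.blq:
            total += _blq_mass_ng(g, assay, blq_policy)
            n_blq += 1
        else:
            total += g.drug_mass_ng
    censored_fraction = n_blq / len(groups)
    if n_blq == len(groups):
        warnings.warn(
            f"site {groups[0].site_id}: all groups below LOQ", AllCensoredWarning
        )
    return total / area_cm2, censored_fraction


@dataclass(frozen=True)
class DepthProfile:
    """Per-group depth slabs and concentrations plus per-site totals."""

    subject_id: str
    site_id: str
    depth_top_um: tuple[float, ...]
    depth_bottom_um: tuple[float, ...]
    conc_ng_per_mg: tuple[float, ...]
    conc_ng_per_cm3: tuple[float, ...]
    drug_mass_ng: tuple[float, ...]
    censored: tuple[bool, ...]
    q_ng_cm2: float
    censored_fraction: float
    total_thickness_um: float

    @property
    def depth_mid_um(self) -> tuple[float, ...]:
        return tuple(
            (t + b) / 2.0 for t, b in zip(self.depth_top_um, self.depth_bottom_um)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "site_id": self.site_id,
                "depth_top_um": self.depth_top_um,
                "depth_mid_um": self.depth_mid_um,
                "depth_bottom_um": self.depth_bottom_um,
                "conc_ng_per_mg": self.conc_ng_per_mg,
                "conc_ng_per_cm3": self.conc_ng_per_cm3,
                "drug_mass_ng": self.drug_mass_ng,
                "censored": self.censored,
            }
        )


def build_profile(
    records: list[TapeStripRecord],
    groups: list[StripGroup],
    assay: AssayConfig = AssayConfig(),
    blq_policy: str = "zero",
) -> DepthProfile:
    """Assemble the depth profile for one site from its tapes and groups.

    The slabs tile [0, total removed thickness] exactly; slab boundaries are
    the cumulative thickness at group edges.  All strips count toward Q.
    """
    if not records or not groups:
        raise ValueError("need records and groups for one site")
    site = {(r.subject_id, r.site_id) for r in records} | {
        (g.subject_id, g.site_id) for g in groups
    }
    if len(site) != 1:
        raise ValueError(f"records/groups span multiple sites: {sorted(site)}")
    subject_id, site_id = next(iter(site))
    area = records[0].area_cm2
    density = assay.sc_density_g_cm3

    by_index = {r.strip_index: r for r in records}
    # cumulative depth after each strip
    cum = {0: 0.0}
    depth = 0.0
    for i in sorted(by_index):
        depth += thickness_from_mass(by_index[i].sc_mass_mg, area, density)
        cum[i] = depth

    groups = sorted(groups, key=lambda g: g.strip_indices[0])
    tops, bottoms, conc_mg, conc_cm3, masses, flags = [], [], [], [], [], []
    for g in groups:
        top = cum[g.strip_indices[0] - 1]
        bottom = cum[g.strip_indices[-1]]
        c_per_mg, censored = group_concentration(g, assay, blq_policy)
        # ng/mg SC -> ng/cm3 via density (g/cm3 = 1000 mg/cm3)
        c_per_cm3 = c_per_mg * density * 1000.0
        mass = c_per_mg * g.sc_mass_total_mg
        tops.append(top)
        bottoms.append(bottom)
        conc_mg.append(c_per_mg)
        conc_cm3.append(c_per_cm3)
        masses.append(mass)
        flags.append(censored)

    q, censored_fraction = site_Q(groups, area, assay, blq_policy)
    return DepthProfile(
        subject_id=subject_id,
        site_id=site_id,
        depth_top_um=tuple(tops),
        depth_bottom_um=tuple(bottoms),
        conc_ng_per_mg=tuple(conc_mg),
        conc_ng_per_cm3=tuple(conc_cm3),
        drug_mass_ng=tuple(masses),
        censored=tuple(flags),
        q_ng_cm2=q,
        censored_fraction=censored_fraction,
        total_thickness_um=depth,
    )
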