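"""Radiotherapy demand and per-linac workload.

Population is converted into annual malignant-equivalent cases (MEC) using
national incidence assumptions: 250 malignant and 320 benign radiotherapy
courses per 100,000 inhabitants per year, with three benign courses weighed
as one malignant-equivalent ("malignant-equivalent benign cases", MEBC).
MEC demand is compared against a sustainable capacity cap of 800 MEC per
linac per year (achievable only under extended working hours).

All internal arithmetic is real-valued; integer truncation or rounding is a
report-formatting concern only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "IncidenceAssumptions",
    "WorkloadSummary",
    "per_linac_cases",
    "mebc",
    "annual_mec_demand",
    "per_linac_workload_report",
    "facility_workload",
]

RoundingMode = Literal["truncate", "nearest"]


@dataclass(frozen=True)
class IncidenceAssumptions:
    """Incidence rates and capacity assumptions of the workload model.

    Defaults are the German national figures: 250 malignant and 320 benign
    courses per 100k inhabitants, 3:1 benign-to-malignant workload
    equivalence, and an 800 MEC/linac/year capacity cap.  ``demand_scale``
    is a multiplicative lever (e.g. < 1 for widespread hypofractionation).
    """

    malignant_per_100k: float = 250.0
    benign_per_100k: float = 320.0
    benign_equivalence: float = 3.0
    mec_cap_per_linac: float = 800.0
    demand_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.malignant_per_100k < 0 or self.benign_per_100k < 0:
            raise ValueError("incidence rates must be >= 0")
        if self.benign_equivalence <= 0:
            raise ValueError("benign_equivalence must be > 0")
        if self.mec_cap_per_linac <= 0:
            raise ValueError("mec_cap_per_linac must be > 0")
        if self.demand_scale < 0:
            raise ValueError("demand_scale must be >= 0")

    @property
    def mec_per_100k(self) -> float:
        """Combined MEC incidence per 100k inhabitants (malignant + MEBC)."""
        return self.malignant_per_100k + self.benign_per_100k / self.benign_equivalence


@dataclass(frozen=True)
class WorkloadSummary:
    """Annual workload of one facility given its catchment population."""

    facility_id: str
    linacs: int
    population: float
    malignant_cases: float
    mebc: float
    mec: float
    mec_per_linac: float
    cap_utilization: float


def per_linac_cases(
    total_cases: float, n_linacs: int, mode: RoundingMode = "truncate"
) -> int:
    """Integer cases per linac (or per any resource unit).

    ``truncate`` (default) floors the quotient, matching per-linac workload
    reporting conventions; ``nearest`` rounds half away from zero, matching
    residents-per-linac/-per-facility table conventions.
    """
    if n_linacs < 1:
        raise ValueError(f"n_linacs must be >= 1, got {n_linacs}")
    q = total_cases / n_linacs
    if mode == "truncate":
        return int(q)
    if mode == "nearest":
        return int(math.floor(q + 0.5))
    raise ValueError(f"mode must be 'truncate' or 'nearest', got {mode!r}")


def mebc(benign_cases: float, equivalence: float = 3.0) -> float:
    """Malignant-equivalent benign cases: benign courses / equivalence ratio."""
    if equivalence <= 0:
        raise ValueError(f"equivalence must be > 0, got {equivalence}")
    return benign_cases / equivalence


def annual_mec_demand(population: float, a: IncidenceAssumptions) -> float:
    """Annual MEC demand generated by a population (real-valued).

    demand = demand_scale * population * (malignant + benign/equivalence) / 100k.
    """
    if population < 0:
        raise ValueError(f"population must be >= 0, got {population}")
    return a.demand_scale * population * a.mec_per_100k / 100_000.0


def per_linac_workload_report(
    malignant_cases: float,
    benign_cases: float,
    n_linacs: int,
    equivalence: float = 3.0,
) -> dict[str, int]:
    """National per-linac workload triple under the truncation convention.

    Reports truncate(malignant/linacs), truncate(benign/linacs) and
    truncate(benign/linacs/equivalence) as MEBC; total MEC per linac is the
    sum of the truncated malignant and MEBC figures (so the printed parts add
    up exactly).
    """
    mal = per_linac_cases(malignant_cases, n_linacs)
    ben = per_linac_cases(benign_cases, n_linacs)
    meb = int(mebc(benign_cases, equivalence) / n_linacs)
    return {"malignant": mal, "benign": ben, "mebc": meb, "mec": mal + meb}


def facility_workload(
    facility, catchment_population: float, a: IncidenceAssumptions
) -> WorkloadSummary:
    """Workload summary of a facility serving ``catchment_population``.

    ``cap_utilization`` may exceed 1.0 — it is flagged downstream, never
    clipped here.
    """
    if catchment_population < 0:
        raise ValueError("catchment_population must be >= 0")
    if facility.linacs < 1:
        raise ValueError("facility must have >= 1 linac")
    scale = a.demand_scale * catchment_population / 100_000.0
    malignant = scale * a.malignant_per_100k
    benign_equiv = scale * a.benign_per_100k / a.benign_equivalence
    mec = malignant + benign_equiv
    per_linac = mec / facility.linacs
    return WorkloadSummary(
        facility_id=facility.facility_id,
        linacs=facility.linacs,
        population=catchment_population,
        malignant_cases=malignant,
        mebc=benign_equiv,
        mec=mec,
        mec_per_linac=per_linac,
        cap_utilization=per_linac / a.mec_cap_per_linac,
    )
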