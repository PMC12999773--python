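"""Redistribution network analysis (ReDNA): facility-closure stress test.

Each facility is closed in turn (closures are independent, never cumulative).
The residents of the closed facility's catchment are reassigned to their next
closest *open* facility by travel time — redistribution always uses the time
criterion, the choice a displaced patient would make, regardless of how the
baseline catchments were drawn.  For every receiving facility the relative
patient increase is classified into four response levels:

- level 1, 0–10%: minor workload change;
- level 2, >10–25%: moderate, compensable by longer working hours;
- level 3, >25–50%: major, compensable by additional workforce;
- level 4, >50%: substantial change in medical management required.

Boundary values 10/25/50 map to the lower level (intervals closed on the
right), so "more than 50%" is exactly level 4.  Receiving facilities are also
checked against the 800 MEC/linac/year capacity cap; a facility already at or
above the cap cannot absorb a neighbour's closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .access import Assignment, assign, catchment_populations, weighted_stat
from .demand import IncidenceAssumptions, facility_workload
from .network import CostMatrix, CostPair, RankedFacilities

__all__ = [
    "Reassignment",
    "IncreaseLevel",
    "ReceiverImpact",
    "ClosureReport",
    "RednaResult",
    "LEVEL_BOUNDS",
    "close_and_reassign",
    "patient_increase",
    "classify_increase",
    "capacity_after",
    "travel_penalty",
    "run_full_redna",
]

#: Right-closed level bounds in percent: [0,10], (10,25], (25,50], (50, inf).
LEVEL_BOUNDS: tuple[tuple[float, float], ...] = (
    (0.0, 10.0),
    (10.0, 25.0),
    (25.0, 50.0),
    (50.0, math.inf),
)


class Move(NamedTuple):
    """One displaced cell: where it goes and at what old/new travel cost."""

    cell_id: str
    new_facility_id: str
    old: CostPair
    new: CostPair


@dataclass
class Reassignment:
    """Outcome of closing one facility: who moves where, and who cannot."""

    closed_facility_id: str
    moves: list[Move]
    displaced_population: int
    unreachable_population: int = 0
    unreachable_cells: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class IncreaseLevel:
    level: int
    bounds: tuple[float, float]


@dataclass(frozen=True)
class ReceiverImpact:
    """Effect of one closure on one receiving facility."""

    receiver_id: str
    baseline_population: int
    added_population: int
    increase_pct: float  # math.inf when baseline catchment was empty
    level: int
    infinite_increase: bool
    mec_per_linac_before: float
    mec_per_linac_after: float
    cap_utilization_after: float
    exceeds_cap: bool


@dataclass
class ClosureReport:
    """Full redistribution outcome of one single-facility closure."""

    closed_facility_id: str
    receivers: list[ReceiverImpact]
    displaced_population: int
    unreachable_population: int
    mean_added_min: float
    median_added_min: float
    mean_relative_pct: float
    no_moves: bool = False


@dataclass
class RednaResult:
    """One ClosureReport per facility, plus network-level vulnerability flags."""

    reports: list[ClosureReport]
    #: closures producing at least one level-4 receiver
    level4_closures: list[str] = field(default_factory=list)
    #: closures pushing at least one receiver past the capacity cap
    cap_exceeded_closures: list[str] = field(default_factory=list)


def close_and_reassign(
    baseline: Assignment,
    ranks: RankedFacilities,
    closed_id: str,
    cells: Sequence,
) -> Reassignment:
    """Reassign the closed facility's catchment to next-closest open facilities.

    Each displaced cell moves to its minimum travel-time facility among the
    remaining open set (ties by ascending facility id).  Cells unreachable
    from every open facility are counted as unreachable population.
    """
    if closed_id not in baseline.open_set:
        raise ValueError(f"facility {closed_id!r} was not open at baseline")
    open_ids = sorted(baseline.open_set - {closed_id})
    if not open_ids:
        raise ValueError("cannot close the only open facility")
    matrix = ranks.matrix
    open_cols = np.array([matrix.facility_ids.index(f) for f in open_ids])
    cell_row = {cid: i for i, cid in enumerate(matrix.cell_ids)}
    open_set = set(open_ids)
    pop = {c.cell_id: c.population for c in cells}
    times = matrix.time_on_time
    # redistribution is by travel time; a distance-criterion ranking cannot
    # be walked, so fall back to the dense time argmin in that case
    walk_ranks = ranks.criterion == "time"

    moves: list[Move] = []
    unreachable: list[str] = []
    displaced_pop = 0
    for cid, fid in baseline.cell_to_facility.items():
        if fid != closed_id:
            continue
        displaced_pop += pop.get(cid, 0)
        i = cell_row[cid]
        new_fid = None
        if walk_ranks:
            for col in ranks.order[i]:
                f = matrix.facility_ids[col]
                if f in open_set and math.isfinite(times[i, col]):
                    new_fid = f
                    break
        if new_fid is None:
            # ranking may be top-k truncated; fall back to a dense argmin
            sub = times[i, open_cols]
            j = int(np.argmin(sub))
            if math.isfinite(sub[j]):
                new_fid = open_ids[j]
        if new_fid is None:
            unreachable.append(cid)
            continue
        moves.append(
            Move(
                cell_id=cid,
                new_facility_id=new_fid,
                old=matrix.pair(cid, closed_id, "time"),
                new=matrix.pair(cid, new_fid, "time"),
            )
        )
    return Reassignment(
        closed_facility_id=closed_id,
        moves=moves,
        displaced_population=displaced_pop,
        unreachable_population=sum(pop.get(c, 0) for c in unreachable),
        unreachable_cells=unreachable,
    )


def patient_increase(baseline_population_b: float, added_population: float) -> float:
    """Relative patient increase at a receiver, in percent of its baseline."""
    if baseline_population_b <= 0:
        raise ValueError("baseline_population_b must be > 0")
    return 100.0 * added_population / baseline_population_b


def classify_increase(pct: float) -> IncreaseLevel:
    """Map a non-negative percent increase to its response level (1-4)."""
    if pct < 0:
        raise ValueError(f"increase percent must be >= 0, got {pct}")
    for level, (lo, hi) in enumerate(LEVEL_BOUNDS, start=1):
        if pct <= hi:
            return IncreaseLevel(level=level, bounds=(lo, hi))
    raise AssertionError("unreachable: level bounds cover [0, inf)")


def capacity_after(
    receiver,
    baseline_pop: float,
    added_pop: float,
    a: IncidenceAssumptions,
) -> tuple[float, float, bool]:
    """Per-linac workload and cap utilization after absorbing ``added_pop``.

    Returns (mec_per_linac_after, cap_utilization_after, exceeds) with
    ``exceeds`` true iff the post-closure per-linac workload is above the cap.
    """
    w = facility_workload(receiver, baseline_pop + added_pop, a)
    return w.mec_per_linac, w.cap_utilization, w.mec_per_linac > a.mec_cap_per_linac


def travel_penalty(
    re: Reassignment, cells: Sequence
) -> tuple[float, float, float]:
    """Population-weighted travel-time penalty for displaced residents.

    Returns (mean added minutes, median added minutes, mean relative percent
    increase).  Relative increases are computed over moves with a positive
    old travel time (a cell co-located with the closed facility has no
    finite relative increase).  Empty reassignments yield zeros.
    """
    if not re.moves:
        return 0.0, 0.0, 0.0
    pop = {c.cell_id: c.population for c in cells}
    deltas = np.array([m.new.time_min - m.old.time_min for m in re.moves])
    weights = np.array([pop.get(m.cell_id, 0) for m in re.moves], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(len(re.moves))
    mean_added = weighted_stat(deltas, weights, "mean")
    median_added = weighted_stat(deltas, weights, "median")
    rel_sel = np.array([m.old.time_min > 0 for m in re.moves])
    if rel_sel.any() and weights[rel_sel].sum() > 0:
        rel = np.array(
            [
                100.0 * (m.new.time_min - m.old.time_min) / m.old.time_min
                for m, s in zip(re.moves, rel_sel)
                if s
            ]
        )
        mean_rel = weighted_stat(rel, weights[rel_sel], "mean")
    else:
        mean_rel = 0.0
    return mean_added, median_added, mean_rel


def closure_report(
    closed_id: str,
    baseline: Assignment,
    catchments: dict[str, int],
    ranks: RankedFacilities,
    cells: Sequence,
    facilities: Sequence,
    a: IncidenceAssumptions,
) -> ClosureReport:
    """Build the full report for one single-facility closure."""
    re = close_and_reassign(baseline, ranks, closed_id, cells)
    pop = {c.cell_id: c.population for c in cells}
    fac_by_id = {f.facility_id: f for f in facilities}
    added: dict[str, int] = {}
    for m in re.moves:
        added[m.new_facility_id] = added.get(m.new_facility_id, 0) + pop.get(m.cell_id, 0)
    receivers: list[ReceiverImpact] = []
    for fid in sorted(added):
        base_pop = catchments.get(fid, 0)
        add_pop = added[fid]
        if base_pop > 0:
            pct = patient_increase(base_pop, add_pop)
            infinite = False
        else:
            pct = math.inf
            infinite = True
        level = 4 if infinite else classify_increase(pct).level
        fac = fac_by_id[fid]
        before = facility_workload(fac, base_pop, a).mec_per_linac
        after, util, exceeds = capacity_after(fac, base_pop, add_pop, a)
        receivers.append(
            ReceiverImpact(
                receiver_id=fid,
                baseline_population=base_pop,
                added_population=add_pop,
                increase_pct=pct,
                level=level,
                infinite_increase=infinite,
                mec_per_linac_before=before,
                mec_per_linac_after=after,
                cap_utilization_after=util,
                exceeds_cap=exceeds,
            )
        )
    mean_added, median_added, mean_rel = travel_penalty(re, cells)
    return ClosureReport(
        closed_facility_id=closed_id,
        receivers=receivers,
        displaced_population=re.displaced_population,
        unreachable_population=re.unreachable_population,
        mean_added_min=mean_added,
        median_added_min=median_added,
        mean_relative_pct=mean_rel,
        no_moves=not re.moves,
    )


def run_full_redna(
    scenario,
    matrix: CostMatrix,
    ranks: RankedFacilities,
    a: IncidenceAssumptions | None = None,
    baseline_criterion: str = "time",
) -> RednaResult:
    """Close every facility in turn and report each redistribution outcome.

    The baseline is restored between iterations — closures are independent.
    Reports are ordered by facility id.
    """
    if a is None:
        a = IncidenceAssumptions()
    if len(scenario.facilities) < 2:
        raise ValueError("ReDNA needs at least 2 facilities")
    baseline = assign(matrix, criterion=baseline_criterion)
    catchments = catchment_populations(baseline, scenario.cells)
    reports = []
    level4: list[str] = []
    cap_exceeded: list[str] = []
    for fac in sorted(scenario.facilities, key=lambda f: f.facility_id):
        rep = closure_report(
            fac.facility_id, baseline, catchments, ranks, scenario.cells,
            scenario.facilities, a,
        )
        reports.append(rep)
        if any(r.level == 4 for r in rep.receivers):
            level4.append(fac.facility_id)
        if any(r.exceeds_cap for r in rep.receivers):
            cap_exceeded.append(fac.facility_id)
    return RednaResult(
        reports=reports,
        level4_closures=level4,
        cap_exceeded_closures=cap_exceeded,
    )
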