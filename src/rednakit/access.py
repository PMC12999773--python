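"""Catchment assignment and population-weighted accessibility statistics.

A catchment is the set of cells whose minimum-cost facility (by travel time
or route distance) is a given facility; catchments are exclusive — every
cell is assigned to exactly one open facility, with ties broken by ascending
facility id.  Accessibility tables report population-weighted mean, median
and 95th-percentile travel time and distance to the rank-n facility,
stratified by region type or administrative unit.

Quantiles use the lower (inverse-CDF) population-weighted definition: the
q-quantile is the smallest value v with cumulative weight(<= v) >= q of the
total, matching "q% of the population reach a facility within v".  Means are
population-weighted by default; an unweighted per-cell ("area") mode is
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .demand import per_linac_cases
from .network import CostMatrix, Criterion, RankedFacilities, rank_facilities

__all__ = [
    "Assignment",
    "AccessStats",
    "assign",
    "catchment_populations",
    "weighted_stat",
    "accessibility_table",
    "relative_increase",
    "state_table",
]

logger = logging.getLogger(__name__)

Weighting = Literal["population", "area"]


@dataclass
class Assignment:
    """Each cell's rank-1 open facility under a criterion."""

    criterion: Criterion
    open_set: frozenset[str]
    cell_to_facility: dict[str, str]
    unassigned: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.cell_to_facility.values()) - self.open_set
        if bad:
            raise ValueError(f"assigned facilities not in open_set: {sorted(bad)}")


@dataclass(frozen=True)
class AccessStats:
    """Accessibility statistics of one (group, rank) stratum."""

    group_key: str
    group: str
    rank: int
    criterion: str
    weighting: str
    mean_time_min: float
    median_time_min: float
    p95_time_min: float
    mean_dist_km: float
    median_dist_km: float
    p95_dist_km: float
    population: float


def assign(
    matrix: CostMatrix,
    criterion: Criterion = "time",
    open_set: Iterable[str] | None = None,
) -> Assignment:
    """Map every cell to its minimum-cost open facility under ``criterion``.

    ``open_set`` defaults to all facilities.  Ties break by ascending
    facility id.  Cells unreachable from every open facility are recorded in
    ``unassigned``, never dropped silently.
    """
    if open_set is None:
        open_ids = list(matrix.facility_ids)
    else:
        open_ids = sorted(set(open_set))
    if not open_ids:
        raise ValueError("open_set must be non-empty")
    missing = set(open_ids) - set(matrix.facility_ids)
    if missing:
        raise KeyError(f"open_set facilities not in matrix: {sorted(missing)}")
    cols = [matrix.facility_ids.index(f) for f in open_ids]
    costs = matrix.primary(criterion)[:, cols]
    best = np.argmin(costs, axis=1)  # first minimum = lowest facility id
    reachable = np.isfinite(costs[np.arange(len(best)), best])
    mapping = {
        cid: open_ids[b]
        for cid, b, ok in zip(matrix.cell_ids, best, reachable)
        if ok
    }
    unassigned = [cid for cid, ok in zip(matrix.cell_ids, reachable) if not ok]
    if unassigned:
        logger.warning("%d cell(s) unreachable from every open facility", len(unassigned))
    return Assignment(
        criterion=criterion,
        open_set=frozenset(open_ids),
        cell_to_facility=mapping,
        unassigned=unassigned,
    )


def catchment_populations(assignment: Assignment, cells: Sequence) -> dict[str, int]:
    """Sum cell populations per assigned facility.

    Every open facility appears, empty catchments with 0.  Unassigned cells
    are excluded (they are listed on the assignment).
    """
    totals = {fid: 0 for fid in sorted(assignment.open_set)}
    for cell in cells:
        fid = assignment.cell_to_facility.get(cell.cell_id)
        if fid is not None:
            totals[fid] += cell.population
    return totals


def weighted_stat(
    values: Sequence[float],
    weights: Sequence[float],
    which: Literal["mean", "median", "p95"],
) -> float:
    """Population-weighted mean or lower inverse-CDF quantile.

    mean = sum(w*v)/sum(w); quantile q = smallest v with cumulative
    weight(<= v)/total >= q (median q=0.5, p95 q=0.95).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be equal-length 1-D sequences")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be > 0")
    if which == "mean":
        return float((v * w).sum() / total)
    q = {"median": 0.5, "p95": 0.95}.get(which)
    if q is None:
        raise ValueError(f"which must be 'mean', 'median' or 'p95', got {which!r}")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum / total, q, side="left"))
    idx = min(idx, len(v) - 1)
    return float(v[order][idx])


def _group_labels(cells: Sequence, group_key: str) -> list[str]:
    if group_key == "ALL":
        return ["ALL"] * len(cells)
    if group_key == "region_type":
        return [c.region_type for c in cells]
    if group_key == "admin_unit":
        return [c.admin_unit for c in cells]
    raise ValueError(f"group_key must be ALL, region_type or admin_unit, got {group_key!r}")


def accessibility_table(
    matrix: CostMatrix,
    cells: Sequence,
    group_key: str = "ALL",
    ranks: Sequence[int] = (1, 2),
    criterion: Criterion = "time",
    weighting: Weighting = "population",
    ranked: RankedFacilities | None = None,
) -> list[AccessStats]:
    """One AccessStats row per (group, rank).

    Statistics are over each cell's rank-n travel cost pair under
    ``criterion``, weighted by cell population (or equally per cell when
    ``weighting='area'``).  Cells with no reachable rank-n facility are
    excluded from that rank with a logged count; empty groups are omitted.
    """
    if ranked is None:
        ranked = rank_facilities(matrix, criterion)
    if any(r < 1 or r > len(matrix.facility_ids) for r in ranks):
        raise ValueError(f"ranks must lie in 1..{len(matrix.facility_ids)}")
    cells = sorted(cells, key=lambda c: c.cell_id)
    if [c.cell_id for c in cells] != list(matrix.cell_ids):
        raise ValueError("cells do not match matrix cell_ids")
    labels = np.array(_group_labels(cells, group_key))
    pops = np.array([c.population for c in cells], dtype=float)
    rows: list[AccessStats] = []
    for rank in ranks:
        t, d = ranked.rank_pair_arrays(rank)
        ok = np.isfinite(t)
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("rank %d: %d cell(s) with no reachable facility excluded", rank, n_bad)
        for group in sorted(set(labels)):
            sel = (labels == group) & ok
            if not sel.any():
                logger.info("group %r empty at rank %d; row omitted", group, rank)
                continue
            w = pops[sel] if weighting == "population" else np.ones(sel.sum())
            if w.sum() <= 0:
                logger.info("group %r has zero weight at rank %d; row omitted", group, rank)
                continue
            rows.append(
                AccessStats(
                    group_key=group_key,
                    group=group,
                    rank=rank,
                    criterion=criterion,
                    weighting=weighting,
                    mean_time_min=weighted_stat(t[sel], w, "mean"),
                    median_time_min=weighted_stat(t[sel], w, "median"),
                    p95_time_min=weighted_stat(t[sel], w, "p95"),
                    mean_dist_km=weighted_stat(d[sel], w, "mean"),
                    median_dist_km=weighted_stat(d[sel], w, "median"),
                    p95_dist_km=weighted_stat(d[sel], w, "p95"),
                    population=float(pops[sel].sum()),
                )
            )
    return rows


def relative_increase(stat_base: float, stat_higher: float) -> float:
    """Percent increase from a base statistic to a higher-rank statistic."""
    if stat_base <= 0:
        raise ValueError(f"stat_base must be > 0, got {stat_base}")
    return 100.0 * (stat_higher - stat_base) / stat_base


def state_table(
    catchments: dict[str, int],
    facilities: Sequence,
    mode: str = "nearest",
) -> pd.DataFrame:
    """Per-administrative-unit resource table from facility catchments.

    For each admin unit: residents within the catchments of its facilities,
    linac and facility counts, residents per linac, residents per facility
    (both nearest-integer by default) and linacs per facility (2 decimals).
    """
    recs = []
    by_unit: dict[str, list] = {}
    for f in facilities:
        by_unit.setdefault(f.admin_unit, []).append(f)
    for unit in sorted(by_unit):
        facs = by_unit[unit]
        residents = sum(catchments.get(f.facility_id, 0) for f in facs)
        linacs = sum(f.linacs for f in facs)
        rocs = len(facs)
        recs.append(
            {
                "admin_unit": unit,
                "residents": residents,
                "linacs": linacs,
                "rocs": rocs,
                "residents_per_linac": per_linac_cases(residents, linacs, mode),
                "residents_per_roc": per_linac_cases(residents, rocs, mode),
                "linacs_per_roc": round(linacs / rocs, 2),
            }
        )
    return pd.DataFrame.from_records(recs)
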