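"""Shortest-path travel-cost engine.

Computes, for every (grid cell, facility) pair, the car travel time and route
distance under two optimality criteria — the fastest route (time-optimal) and
the shortest route (distance-optimal) — and ranks facilities per cell by
either criterion (rank 1 = closest, rank 2 = second-closest, ...).

Travel direction is cell → facility (patients travel to the treatment site);
with one-way edges the single-source searches from each facility therefore
run on the reversed graph.  Unreachable pairs carry an infinite sentinel and
are never silently zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal, NamedTuple

import networkx as nx
import numpy as np

__all__ = [
    "RoadNetwork",
    "CostPair",
    "CostMatrix",
    "RankedFacilities",
    "UNREACHABLE",
    "edge_travel_time",
    "shortest_costs",
    "cost_matrix",
    "rank_facilities",
]

logger = logging.getLogger(__name__)

Criterion = Literal["time", "distance"]

#: Sentinel cost for pairs with no connecting route.
UNREACHABLE = math.inf


def edge_travel_time(length_m: float, speed_kmh: float) -> float:
    """Travel time in minutes for an edge of ``length_m`` at ``speed_kmh``.

    time [min] = length [m] / (speed [km/h] * 1000/60 [m/min]).
    """
    if speed_kmh <= 0:
        raise ValueError(f"speed_kmh must be > 0, got {speed_kmh}")
    if length_m < 0:
        raise ValueError(f"length_m must be >= 0, got {length_m}")
    return length_m / (speed_kmh * 1000.0 / 60.0)


class CostPair(NamedTuple):
    """Travel cost of one route: minutes and route kilometers."""

    time_min: float
    dist_km: float

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.time_min)


@dataclass
class RoadNetwork:
    """Road graph with planar meter coordinates and per-edge speed.

    ``nodes`` maps node id → (x_m, y_m); ``edges`` maps (u, v) →
    (length_m, speed_kmh, oneway).  Two-way edges are stored once and
    traversable in both directions.
    """

    nodes: dict[str, tuple[float, float]]
    edges: dict[tuple[str, str], tuple[float, float, bool]]

    def validate(self) -> None:
        for (u, v), (length_m, speed_kmh, _oneway) in self.edges.items():
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}): endpoint not in nodes")
            if length_m <= 0:
                raise ValueError(f"edge ({u}, {v}): length_m must be > 0")
            if speed_kmh <= 0:
                raise ValueError(f"edge ({u}, {v}): speed_kmh must be > 0")

    def directed_edges(self) -> Iterator[tuple[str, str, float, float]]:
        """Yield (u, v, time_min, dist_km) for every traversable direction."""
        for (u, v), (length_m, speed_kmh, oneway) in self.edges.items():
            t = edge_travel_time(length_m, speed_kmh)
            d = length_m / 1000.0
            yield u, v, t, d
            if not oneway:
                yield v, u, t, d

    def to_digraph(self, reverse: bool = False) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, t, d in self.directed_edges():
            if reverse:
                u, v = v, u
            g.add_edge(u, v, time=t, distance=d)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _companion_key(weight: Criterion) -> str:
    return "distance" if weight == "time" else "time"


def shortest_costs(
    network: RoadNetwork | nx.DiGraph,
    source: str,
    weight: Criterion = "time",
) -> dict[str, CostPair]:
    """Single-source shortest costs under ``weight`` (Dijkstra), all nodes.

    Returns node → CostPair.  The optimised quantity is exact; the companion
    quantity (route km for a time-optimal path, route minutes for a
    distance-optimal one) is accumulated along the returned optimal path.
    Unreachable nodes carry the infinite sentinel in both slots.
    """
    g = network.to_digraph() if isinstance(network, RoadNetwork) else network
    if source not in g:
        raise KeyError(f"source node {source!r} not in network")
    if weight not in ("time", "distance"):
        raise ValueError(f"weight must be 'time' or 'distance', got {weight!r}")
    comp_key = _companion_key(weight)
    dist, paths = nx.single_source_dijkstra(g, source, weight=weight)
    out: dict[str, CostPair] = {}
    for node in g.nodes:
        if node not in dist:
            out[node] = CostPair(UNREACHABLE, UNREACHABLE)
            continue
        path = paths[node]
        companion = sum(
            g.edges[a, b][comp_key] for a, b in zip(path[:-1], path[1:])
        )
        primary = dist[node]
        if weight == "time":
            out[node] = CostPair(primary, companion)
        else:
            out[node] = CostPair(companion, primary)
    return out


@dataclass
class CostMatrix:
    """(cell x facility) travel costs under both route-optimality criteria.

    Four dense float arrays of shape (n_cells, n_facilities):

    - ``time_on_time`` / ``dist_on_time``: minutes and route km of the
      time-optimal (fastest) route;
    - ``dist_on_dist`` / ``time_on_dist``: route km and minutes of the
      distance-optimal (shortest) route.

    Costs are travel from the cell's node to the facility's node.
    Facility ids are kept in ascending order so that stable sorts break cost
    ties by facility id.
    """

    cell_ids: list[str]
    facility_ids: list[str]
    time_on_time: np.ndarray
    dist_on_time: np.ndarray
    dist_on_dist: np.ndarray
    time_on_dist: np.ndarray
    offset_min: float = 0.0
    _cell_index: dict[str, int] = field(init=False, repr=False)
    _fac_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n, m = len(self.cell_ids), len(self.facility_ids)
        for arr in (self.time_on_time, self.dist_on_time, self.dist_on_dist, self.time_on_dist):
            if arr.shape != (n, m):
                raise ValueError(f"cost array shape {arr.shape} != ({n}, {m})")
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}
        self._fac_index = {f: j for j, f in enumerate(self.facility_ids)}

    def primary(self, criterion: Criterion) -> np.ndarray:
        """The optimised cost array for a criterion (minutes or km)."""
        if criterion == "time":
            return self.time_on_time
        if criterion == "distance":
            return self.dist_on_dist
        raise ValueError(f"criterion must be 'time' or 'distance', got {criterion!r}")

    def pair(self, cell_id: str, facility_id: str, criterion: Criterion = "time") -> CostPair:
        i, j = self._cell_index[cell_id], self._fac_index[facility_id]
        if criterion == "time":
            return CostPair(float(self.time_on_time[i, j]), float(self.dist_on_time[i, j]))
        return CostPair(float(self.time_on_dist[i, j]), float(self.dist_on_dist[i, j]))

    def with_offset(self, minutes: float = 5.0) -> "CostMatrix":
        """Copy with a flat access/egress/parking offset added to travel times.

        The offset applies to reachable entries only; route distances are
        unchanged.  Default 5 minutes, the conventional flat compensation for
        access, egress and parking-search time.
        """
        def shift(arr: np.ndarray) -> np.ndarray:
            out = arr.copy()
            out[np.isfinite(out)] += minutes
            return out

        return CostMatrix(
            cell_ids=list(self.cell_ids),
            facility_ids=list(self.facility_ids),
            time_on_time=shift(self.time_on_time),
            dist_on_time=self.dist_on_time.copy(),
            dist_on_dist=self.dist_on_dist.copy(),
            time_on_dist=shift(self.time_on_dist),
            offset_min=self.offset_min + minutes,
        )


@dataclass
class RankedFacilities:
    """Per-cell facility ordering by ascending cost under one criterion.

    ``order[i, r]`` is the column index (into ``facility_ids``) of the
    rank-(r+1) facility of cell i; ties are broken by ascending facility id.
    ``matrix`` is retained so redistribution can fall back to a dense argmin
    when a top-k-truncated ranking is exhausted.
    """

    criterion: Criterion
    cell_ids: list[str]
    facility_ids: list[str]
    order: np.ndarray
    matrix: CostMatrix

    def facilities_for(self, cell_id: str) -> list[str]:
        i = self.cell_ids.index(cell_id)
        return [self.facility_ids[j] for j in self.order[i]]

    def rank_cost(self, rank: int) -> np.ndarray:
        """Cost of each cell's rank-n facility (1-based rank), inf if absent."""
        if not 1 <= rank <= self.order.shape[1]:
            raise ValueError(f"rank {rank} outside 1..{self.order.shape[1]}")
        costs = self.matrix.primary(self.criterion)
        rows = np.arange(len(self.cell_ids))
        return costs[rows, self.order[:, rank - 1]]

    def rank_pair_arrays(self, rank: int) -> tuple[np.ndarray, np.ndarray]:
        """(time_min, dist_km) of each cell's rank-n route under the criterion."""
        rows = np.arange(len(self.cell_ids))
        cols = self.order[:, rank - 1]
        if self.criterion == "time":
            return self.matrix.time_on_time[rows, cols], self.matrix.dist_on_time[rows, cols]
        return self.matrix.time_on_dist[rows, cols], self.matrix.dist_on_dist[rows, cols]


def cost_matrix(scenario, max_entries: int = 10_000_000) -> CostMatrix:
    """Compute the full (cell x facility) cost matrix for both criteria.

    Runs one single-source Dijkstra per facility and criterion on the
    reversed graph, so entries are costs of travel from each cell's node to
    the facility.  Cells unreachable from every facility trigger a structured
    warning listing their ids; the matrix is still returned with infinite
    sentinels.
    """
    n_cells, n_fac = len(scenario.cells), len(scenario.facilities)
    if n_cells * n_fac > max_entries:
        raise ValueError(
            f"dense matrix of {n_cells * n_fac} entries exceeds max_entries="
            f"{max_entries}; raise the limit or reduce the scenario"
        )
    cells = sorted(scenario.cells, key=lambda c: c.cell_id)
    facilities = sorted(scenario.facilities, key=lambda f: f.facility_id)
    cell_ids = [c.cell_id for c in cells]
    facility_ids = [f.facility_id for f in facilities]
    g_rev = scenario.network.to_digraph(reverse=True)

    shape = (n_cells, n_fac)
    t_t = np.full(shape, UNREACHABLE)
    d_t = np.full(shape, UNREACHABLE)
    d_d = np.full(shape, UNREACHABLE)
    t_d = np.full(shape, UNREACHABLE)
    for j, fac in enumerate(facilities):
        by_time = shortest_costs(g_rev, fac.node_id, weight="time")
        by_dist = shortest_costs(g_rev, fac.node_id, weight="distance")
        for i, cell in enumerate(cells):
            pt = by_time[cell.node_id]
            pd = by_dist[cell.node_id]
            t_t[i, j], d_t[i, j] = pt.time_min, pt.dist_km
            t_d[i, j], d_d[i, j] = pd.time_min, pd.dist_km

    orphan = [cid for i, cid in enumerate(cell_ids) if not np.isfinite(t_t[i]).any()]
    if orphan:
        warnings.warn(
            f"{len(orphan)} cell(s) unreachable from every facility: {orphan[:20]}",
            stacklevel=2,
        )
        logger.warning("unreachable cells: %s", orphan)
    return CostMatrix(
        cell_ids=cell_ids,
        facility_ids=facility_ids,
        time_on_time=t_t,
        dist_on_time=d_t,
        dist_on_dist=d_d,
        time_on_dist=t_d,
    )


def rank_facilities(
    matrix: CostMatrix, criterion: Criterion = "time", k: int | None = None
) -> RankedFacilities:
    """Rank facilities per cell by ascending cost under ``criterion``.

    Ties break by ascending facility id (matrix columns are id-sorted and the
    sort is stable).  ``k`` truncates the ranking to the top k facilities.
    """
    costs = matrix.primary(criterion)
    order = np.argsort(costs, axis=1, kind="stable")
    if k is not None:
        order = order[:, :k]
    return RankedFacilities(
        criterion=criterion,
        cell_ids=list(matrix.cell_ids),
        facility_ids=list(matrix.facility_ids),
        order=order,
        matrix=matrix,
    )
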