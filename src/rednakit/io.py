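"""CSV/GeoJSON round-tripping of scenarios, matrices and result tables.

All files are UTF-8 CSV with a header row.  Readers validate schemas and
referential integrity and report violations with file, row and column.
Report floats are formatted at a fixed granularity (minutes/km and percents
to 1 decimal, cap utilization to 3 decimals); all in-memory math stays
double precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .access import AccessStats
from .demand import WorkloadSummary
from .network import CostMatrix, RoadNetwork, rank_facilities
from .redna import ClosureReport
from .scenario import Facility, GridCell, Scenario

__all__ = [
    "SchemaError",
    "read_scenario",
    "write_scenario",
    "write_cells_geojson",
    "write_cost_matrix",
    "read_cost_matrix",
    "write_access_stats",
    "write_workload",
    "write_redna_reports",
]

SCENARIO_FILES = ("nodes.csv", "edges.csv", "cells.csv", "facilities.csv")


@dataclass
class SchemaError(ValueError):
    """A structured input-validation failure."""

    file: str
    row: int | None
    column: str | None
    reason: str

    def __str__(self) -> str:
        loc = self.file
        if self.row is not None:
            loc += f", row {self.row}"
        if self.column:
            loc += f", column {self.column}"
        return f"{loc}: {self.reason}"


def _read_csv(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(str(path), None, None, "file not found")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(str(path), None, ",".join(missing), "missing column(s)")
    return df


def _num(df: pd.DataFrame, col: str, path: Path, kind=float) -> list:
    out = []
    for row, raw in enumerate(df[col], start=2):  # header is row 1
        try:
            out.append(kind(raw))
        except (TypeError, ValueError):
            raise SchemaError(str(path), row, col, f"not a valid {kind.__name__}: {raw!r}")
    return out


def read_scenario(directory: str | Path) -> Scenario:
    """Read and fully validate a scenario from its four CSV files."""
    d = Path(directory)
    nodes_df = _read_csv(d / "nodes.csv", ["node_id", "x_m", "y_m"])
    nodes: dict[str, tuple[float, float]] = {}
    xs = _num(nodes_df, "x_m", d / "nodes.csv")
    ys = _num(nodes_df, "y_m", d / "nodes.csv")
    for row, (nid, x, y) in enumerate(zip(nodes_df["node_id"], xs, ys), start=2):
        if nid in nodes:
            raise SchemaError("nodes.csv", row, "node_id", f"duplicate node_id {nid!r}")
        nodes[nid] = (x, y)

    edges_df = _read_csv(d / "edges.csv", ["u", "v", "length_m", "speed_kmh", "oneway"])
    lengths = _num(edges_df, "length_m", d / "edges.csv")
    speeds = _num(edges_df, "speed_kmh", d / "edges.csv")
    oneways = _num(edges_df, "oneway", d / "edges.csv", int)
    edges: dict[tuple[str, str], tuple[float, float, bool]] = {}
    for row, (u, v, ln, sp, ow) in enumerate(
        zip(edges_df["u"], edges_df["v"], lengths, speeds, oneways), start=2
    ):
        for col, endpoint in (("u", u), ("v", v)):
            if endpoint not in nodes:
                raise SchemaError("edges.csv", row, col, f"unknown node {endpoint!r}")
        if ln <= 0:
            raise SchemaError("edges.csv", row, "length_m", f"must be > 0, got {ln}")
        if sp <= 0:
            raise SchemaError("edges.csv", row, "speed_kmh", f"must be > 0, got {sp}")
        if ow not in (0, 1):
            raise SchemaError("edges.csv", row, "oneway", f"must be 0 or 1, got {ow}")
        edges[(u, v)] = (ln, sp, bool(ow))
    network = RoadNetwork(nodes=nodes, edges=edges)
    network.validate()

    cells_df = _read_csv(d / "cells.csv", ["cell_id", "node_id", "population", "region_type", "admin_unit"])
    pops = _num(cells_df, "population", d / "cells.csv", int)
    cells: list[GridCell] = []
    seen: set[str] = set()
    for row, (cid, nid, p, rt, au) in enumerate(
        zip(cells_df["cell_id"], cells_df["node_id"], pops,
            cells_df["region_type"], cells_df["admin_unit"]), start=2,
    ):
        if cid in seen:
            raise SchemaError("cells.csv", row, "cell_id", f"duplicate cell_id {cid!r}")
        seen.add(cid)
        if nid not in nodes:
            raise SchemaError("cells.csv", row, "node_id", f"unknown node {nid!r}")
        if p < 0:
            raise SchemaError("cells.csv", row, "population", f"must be >= 0, got {p}")
        try:
            cells.append(GridCell(cid, nid, p, rt, au))
        except ValueError as exc:
            raise SchemaError("cells.csv", row, "region_type", str(exc))

    fac_df = _read_csv(d / "facilities.csv", ["facility_id", "node_id", "linacs", "name", "admin_unit"])
    linacs = _num(fac_df, "linacs", d / "facilities.csv", int)
    facilities: list[Facility] = []
    seen = set()
    for row, (fid, nid, ln, name, au) in enumerate(
        zip(fac_df["facility_id"], fac_df["node_id"], linacs,
            fac_df["name"], fac_df["admin_unit"]), start=2,
    ):
        if fid in seen:
            raise SchemaError("facilities.csv", row, "facility_id", f"duplicate facility_id {fid!r}")
        seen.add(fid)
        if nid not in nodes:
            raise SchemaError("facilities.csv", row, "node_id", f"unknown node {nid!r}")
        if ln < 1:
            raise SchemaError("facilities.csv", row, "linacs", f"must be >= 1, got {ln}")
        facilities.append(Facility(fid, nid, ln, name, au))

    scenario = Scenario(network=network, cells=cells, facilities=facilities)
    scenario.validate()
    return scenario


def write_scenario(scenario: Scenario, directory: str | Path) -> list[Path]:
    """Write nodes/edges/cells/facilities CSVs; returns the written paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    nodes = pd.DataFrame(
        [(nid, x, y) for nid, (x, y) in sorted(scenario.network.nodes.items())],
        columns=["node_id", "x_m", "y_m"],
    )
    edges = pd.DataFrame(
        [
            (u, v, ln, sp, int(ow))
            for (u, v), (ln, sp, ow) in sorted(scenario.network.edges.items())
        ],
        columns=["u", "v", "length_m", "speed_kmh", "oneway"],
    )
    cells = pd.DataFrame(
        [
            (c.cell_id, c.node_id, c.population, c.region_type, c.admin_unit)
            for c in sorted(scenario.cells, key=lambda c: c.cell_id)
        ],
        columns=["cell_id", "node_id", "population", "region_type", "admin_unit"],
    )
    facs = pd.DataFrame(
        [
            (f.facility_id, f.node_id, f.linacs, f.name, f.admin_unit)
            for f in sorted(scenario.facilities, key=lambda f: f.facility_id)
        ],
        columns=["facility_id", "node_id", "linacs", "name", "admin_unit"],
    )
    for name, df in (
        ("nodes.csv", nodes), ("edges.csv", edges),
        ("cells.csv", cells), ("facilities.csv", facs),
    ):
        p = d / name
        df.to_csv(p, index=False)
        paths.append(p)
    meta = d / "meta.json"
    meta.write_text(json.dumps(scenario.meta, indent=2, sort_keys=True) + "\n")
    paths.append(meta)
    return paths


def write_cells_geojson(scenario: Scenario, path: str | Path) -> Path:
    """Point-feature GeoJSON of cells and facilities (planar coordinates)."""
    feats = []
    for c in sorted(scenario.cells, key=lambda c: c.cell_id):
        x, y = scenario.network.nodes[c.node_id]
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {
                    "kind": "cell", "cell_id": c.cell_id, "population": c.population,
                    "region_type": c.region_type, "admin_unit": c.admin_unit,
                },
            }
        )
    for f in sorted(scenario.facilities, key=lambda f: f.facility_id):
        x, y = scenario.network.nodes[f.node_id]
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {
                    "kind": "facility", "facility_id": f.facility_id,
                    "linacs": f.linacs, "name": f.name, "admin_unit": f.admin_unit,
                },
            }
        )
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
    return path


def write_cost_matrix(matrix: CostMatrix, path: str | Path) -> Path:
    """Long-format cost CSV with per-criterion ranks."""
    rt = rank_facilities(matrix, "time")
    rd = rank_facilities(matrix, "distance")
    n, m = len(matrix.cell_ids), len(matrix.facility_ids)
    rank_time = np.empty((n, m), dtype=int)
    rank_dist = np.empty((n, m), dtype=int)
    rows = np.arange(n)[:, None]
    rank_time[rows, rt.order] = np.arange(1, m + 1)
    rank_dist[rows, rd.order] = np.arange(1, m + 1)
    df = pd.DataFrame(
        {
            "cell_id": np.repeat(matrix.cell_ids, m),
            "facility_id": np.tile(matrix.facility_ids, n),
            "rank_time": rank_time.ravel(),
            "time_min": matrix.time_on_time.ravel(),
            "dist_km_on_time_path": matrix.dist_on_time.ravel(),
            "rank_dist": rank_dist.ravel(),
            "dist_km": matrix.dist_on_dist.ravel(),
            "time_min_on_dist_path": matrix.time_on_dist.ravel(),
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_cost_matrix(path: str | Path) -> CostMatrix:
    """Rebuild a CostMatrix from the long-format cost CSV."""
    df = pd.read_csv(path, dtype={"cell_id": str, "facility_id": str})
    cell_ids = sorted(df["cell_id"].unique())
    facility_ids = sorted(df["facility_id"].unique())
    ci = {c: i for i, c in enumerate(cell_ids)}
    fi = {f: j for j, f in enumerate(facility_ids)}
    shape = (len(cell_ids), len(facility_ids))
    arrays = {
        k: np.full(shape, np.inf)
        for k in ("time_on_time", "dist_on_time", "dist_on_dist", "time_on_dist")
    }
    i = df["cell_id"].map(ci).to_numpy()
    j = df["facility_id"].map(fi).to_numpy()
    arrays["time_on_time"][i, j] = df["time_min"].to_numpy()
    arrays["dist_on_time"][i, j] = df["dist_km_on_time_path"].to_numpy()
    arrays["dist_on_dist"][i, j] = df["dist_km"].to_numpy()
    arrays["time_on_dist"][i, j] = df["time_min_on_dist_path"].to_numpy()
    return CostMatrix(cell_ids=cell_ids, facility_ids=facility_ids, **arrays)


def _fmt(x: float, decimals: int) -> str:
    if not np.isfinite(x):
        return "inf"
    return f"{x:.{decimals}f}"


def write_access_stats(stats: Sequence[AccessStats], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "group_key": s.group_key,
                "group": s.group,
                "rank": s.rank,
                "criterion": s.criterion,
                "weighting": s.weighting,
                "mean_time_min": _fmt(s.mean_time_min, 1),
                "median_time_min": _fmt(s.median_time_min, 1),
                "p95_time_min": _fmt(s.p95_time_min, 1),
                "mean_dist_km": _fmt(s.mean_dist_km, 1),
                "median_dist_km": _fmt(s.median_dist_km, 1),
                "p95_dist_km": _fmt(s.p95_dist_km, 1),
                "population": int(s.population),
            }
            for s in stats
        ],
        columns=[
            "group_key", "group", "rank", "criterion", "weighting",
            "mean_time_min", "median_time_min", "p95_time_min",
            "mean_dist_km", "median_dist_km", "p95_dist_km", "population",
        ],
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_workload(summaries: Sequence[WorkloadSummary], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "facility_id": w.facility_id,
                "linacs": w.linacs,
                "population": int(w.population),
                "mec": _fmt(w.mec, 1),
                "mec_per_linac": _fmt(w.mec_per_linac, 1),
                "cap_utilization": _fmt(w.cap_utilization, 3),
            }
            for w in summaries
        ],
        columns=["facility_id", "linacs", "population", "mec", "mec_per_linac", "cap_utilization"],
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_redna_reports(
    reports: Sequence[ClosureReport], outdir: str | Path
) -> tuple[Path, Path]:
    """Write receiver-level and penalty-level ReDNA CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recv_rows = []
    pen_rows = []
    for rep in reports:
        for r in rep.receivers:
            recv_rows.append(
                {
                    "closed_facility_id": rep.closed_facility_id,
                    "receiver_id": r.receiver_id,
                    "baseline_pop": r.baseline_population,
                    "added_pop": r.added_population,
                    "increase_pct": _fmt(r.increase_pct, 1),
                    "level": r.level,
                    "mec_per_linac_after": _fmt(r.mec_per_linac_after, 1),
                    "cap_utilization_after": _fmt(r.cap_utilization_after, 3),
                    "exceeds_cap": int(r.exceeds_cap),
                }
            )
        pen_rows.append(
            {
                "closed_facility_id": rep.closed_facility_id,
                "displaced_pop": rep.displaced_population,
                "mean_added_min": _fmt(rep.mean_added_min, 1),
                "median_added_min": _fmt(rep.median_added_min, 1),
                "mean_relative_pct": _fmt(rep.mean_relative_pct, 1),
                "unreachable_pop": rep.unreachable_population,
            }
        )
    recv_cols = [
        "closed_facility_id", "receiver_id", "baseline_pop", "added_pop",
        "increase_pct", "level", "mec_per_linac_after",
        "cap_utilization_after", "exceeds_cap",
    ]
    pen_cols = [
        "closed_facility_id", "displaced_pop", "mean_added_min",
        "median_added_min", "mean_relative_pct", "unreachable_pop",
    ]
    report_path = outdir / "redna_report.csv"
    pen_path = outdir / "redna_penalties.csv"
    pd.DataFrame(recv_rows, columns=recv_cols).to_csv(report_path, index=False)
    pd.DataFrame(pen_rows, columns=pen_cols).to_csv(pen_path, index=False)
    return report_path, pen_path
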