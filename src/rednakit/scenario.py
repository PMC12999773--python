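"""Domain entities and a seeded synthetic scenario generator.

The toolkit analyses the accessibility of treatment facilities (radiation
oncology centers, ROCs) over a road network.  Real inputs are a census-style
population grid, a road graph with travel speeds, and a facility registry with
linac counts.  Because no such dataset ships with the package, this module can
generate a country-like synthetic scenario: dense urban population clusters on
a lattice road network with mixed speed classes, a sparse rural background,
and facilities placed proportional to population with a linac-count
distribution matching the German national census of ROCs (133 of 337
single-linac, 128 with two, 21 with four or more; the 3-linac stratum is the
remainder, 55).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import RoadNetwork

__all__ = [
    "GridCell",
    "Facility",
    "Scenario",
    "SynthParams",
    "REGION_TYPES",
    "DEFAULT_LINAC_PMF",
    "generate_network",
    "generate_population",
    "generate_facilities",
    "generate_scenario",
]

#: Urban-to-rural regional typology labels, densest (RS71, metropolis) to
#: sparsest (RS77, small-town/village area in a rural region).
REGION_TYPES = ("RS71", "RS72", "RS73", "RS74", "RS75", "RS76", "RS77")

#: Linac-count distribution of the German ROC census: 133/337 single-linac,
#: 128/337 two-linac, 55/337 three-linac (inferred remainder), 21/337 with
#: four or more (modelled as exactly four).  Mean = 645/337 ≈ 1.914.
DEFAULT_LINAC_PMF: Mapping[int, float] = {
    1: 133 / 337,
    2: 128 / 337,
    3: 55 / 337,
    4: 21 / 337,
}


class ScenarioValidationError(ValueError):
    """A scenario entity violates an invariant; the message names the field."""


@dataclass(frozen=True)
class GridCell:
    """An inhabited census grid cell anchored to a road-network node."""

    cell_id: str
    node_id: str
    population: int
    region_type: str
    admin_unit: str

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ScenarioValidationError(
                f"cell {self.cell_id}: population must be >= 0, got {self.population}"
            )
        if self.region_type not in REGION_TYPES:
            raise ScenarioValidationError(
                f"cell {self.cell_id}: region_type {self.region_type!r} not in {REGION_TYPES}"
            )


@dataclass(frozen=True)
class Facility:
    """A treatment site (ROC) with one or more linear accelerators."""

    facility_id: str
    node_id: str
    linacs: int
    name: str = ""
    admin_unit: str = ""

    def __post_init__(self) -> None:
        if self.linacs < 1:
            raise ScenarioValidationError(
                f"facility {self.facility_id}: linacs must be >= 1, got {self.linacs}"
            )


@dataclass
class Scenario:
    """A road network plus population cells and facilities anchored to it."""

    network: RoadNetwork
    cells: list[GridCell]
    facilities: list[Facility]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check referential integrity and id uniqueness; raise on violation."""
        nodes = self.network.nodes
        cell_ids = [c.cell_id for c in self.cells]
        if len(set(cell_ids)) != len(cell_ids):
            raise ScenarioValidationError("duplicate cell_id in scenario")
        fac_ids = [f.facility_id for f in self.facilities]
        if len(set(fac_ids)) != len(fac_ids):
            raise ScenarioValidationError("duplicate facility_id in scenario")
        for c in self.cells:
            if c.node_id not in nodes:
                raise ScenarioValidationError(
                    f"cell {c.cell_id}: node_id {c.node_id!r} not in network"
                )
        for f in self.facilities:
            if f.node_id not in nodes:
                raise ScenarioValidationError(
                    f"facility {f.facility_id}: node_id {f.node_id!r} not in network"
                )

    @property
    def total_population(self) -> int:
        return int(sum(c.population for c in self.cells))


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic country-like scenario generator.

    Defaults describe a scaled-down national scenario: a 40x40 road lattice
    at 2 km spacing (an 80 km x 80 km domain), three urban clusters, 4.8 M
    inhabitants and 20 facilities — roughly preserving the German ratio of
    ~128,000 residents per linac so that baseline per-linac workloads sit in
    a realistic range below the 800-MEC capacity cap.
    """

    lattice_n: int = 40
    spacing_m: float = 2000.0
    #: (speed_kmh, probability) classes for edge speeds; urban streets,
    #: country roads and fast arterials.
    speed_classes_kmh: Sequence[tuple[float, float]] = (
        (50.0, 0.5),
        (80.0, 0.3),
        (100.0, 0.2),
    )
    n_urban_centers: int = 3
    urban_sigma_m: float = 6000.0
    rural_density: float = 20.0
    total_population: int = 4_800_000
    n_facilities: int = 20
    linac_pmf: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LINAC_PMF)
    )
    seed: int = 0
    #: Cumulative population-density quantile cut points between RS71..RS77,
    #: densest first; six cuts partition the cells into seven strata with the
    #: metropolis stratum the smallest.
    region_quantile_cuts: Sequence[float] = (0.05, 0.15, 0.30, 0.50, 0.70, 0.85)
    #: Number of vertical admin-unit stripes standing in for federal states.
    n_admin_units: int = 4

    def validate(self) -> None:
        if self.lattice_n < 2:
            raise ScenarioValidationError("lattice_n must be >= 2")
        if self.spacing_m <= 0:
            raise ScenarioValidationError("spacing_m must be > 0")
        probs = [p for _, p in self.speed_classes_kmh]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ScenarioValidationError("speed_classes_kmh probabilities must sum to 1")
        if any(s <= 0 for s, _ in self.speed_classes_kmh):
            raise ScenarioValidationError("speed_classes_kmh speeds must be > 0")
        if self.total_population <= 0:
            raise ScenarioValidationError("total_population must be > 0")
        if self.n_facilities <= 0:
            raise ScenarioValidationError("n_facilities must be > 0")
        if self.n_urban_centers < 0:
            raise ScenarioValidationError("n_urban_centers must be >= 0")
        if self.rural_density < 0:
            raise ScenarioValidationError("rural_density must be >= 0")
        pmf_total = sum(self.linac_pmf.values())
        if abs(pmf_total - 1.0) > 1e-9:
            raise ScenarioValidationError("linac_pmf probabilities must sum to 1")
        if any(k < 1 for k in self.linac_pmf):
            raise ScenarioValidationError("linac_pmf keys must be >= 1 linac")
        cuts = list(self.region_quantile_cuts)
        if len(cuts) != len(REGION_TYPES) - 1 or sorted(cuts) != cuts or not all(
            0.0 < c < 1.0 for c in cuts
        ):
            raise ScenarioValidationError(
                "region_quantile_cuts must be 6 increasing values in (0, 1)"
            )
        if self.n_admin_units < 1:
            raise ScenarioValidationError("n_admin_units must be >= 1")


def _node_id(i: int, j: int) -> str:
    return f"n{i}_{j}"


def generate_network(params: SynthParams) -> RoadNetwork:
    """Build a connected lattice road network with seeded edge speed classes.

    Every edge has length ``spacing_m``; its speed is drawn i.i.d. from
    ``speed_classes_kmh``.  Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, s = params.lattice_n, params.spacing_m
    nodes = {_node_id(i, j): (j * s, i * s) for i in range(n) for j in range(n)}
    edge_list: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(n):
            if j + 1 < n:
                edge_list.append((_node_id(i, j), _node_id(i, j + 1)))
            if i + 1 < n:
                edge_list.append((_node_id(i, j), _node_id(i + 1, j)))
    speeds = [s for s, _ in params.speed_classes_kmh]
    probs = [p for _, p in params.speed_classes_kmh]
    drawn = rng.choice(speeds, size=len(edge_list), p=probs)
    edges = {
        (u, v): (s, float(sp), False) for (u, v), sp in zip(edge_list, drawn)
    }
    return RoadNetwork(nodes=nodes, edges=edges)


def _intensity(params: SynthParams, network: RoadNetwork, rng: np.random.Generator):
    """Population intensity per node: Gaussian urban kernels + rural floor."""
    node_ids = sorted(network.nodes)
    xy = np.array([network.nodes[nid] for nid in node_ids])
    intensity = np.full(len(node_ids), float(params.rural_density))
    if params.n_urban_centers > 0:
        centers = xy[
            rng.choice(len(node_ids), size=params.n_urban_centers, replace=False)
        ]
        # Kernel amplitude: urban population dominates the rural floor by
        # an order of magnitude at the center, as in real census grids.
        amp = 10.0 * max(params.rural_density, 1.0)
        sig2 = params.urban_sigma_m**2
        for cx, cy in centers:
            d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
            intensity += amp * np.exp(-d2 / (2.0 * sig2))
    return node_ids, xy, intensity


def _rescale_to_total(pop: np.ndarray, total: int) -> np.ndarray:
    """Integer-rescale draws so they sum exactly to ``total`` (largest remainder)."""
    cur = pop.sum()
    if cur == 0:
        # degenerate draw: spread evenly
        base = np.full(len(pop), total // len(pop), dtype=np.int64)
        base[: total % len(pop)] += 1
        return base
    scaled = pop * (total / cur)
    floored = np.floor(scaled).astype(np.int64)
    remainder = int(total - floored.sum())
    if remainder > 0:
        frac = scaled - floored
        order = np.argsort(-frac, kind="stable")
        floored[order[:remainder]] += 1
    return floored


def generate_population(
    params: SynthParams, network: RoadNetwork
) -> list[GridCell]:
    """One inhabited cell per network node, Poisson around the kernel intensity.

    Populations are integer-rescaled so they sum exactly to
    ``total_population``.  Region types are assigned by smoothed
    population-density quantiles (densest cells RS71, sparsest RS77); admin
    units are vertical stripes of the lattice.  Deterministic given seed.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    node_ids, xy, intensity = _intensity(params, network, rng)
    # Scale intensity to the target before the Poisson draw so counts are
    # census-like; then rescale exactly.
    intensity = intensity * (params.total_population / intensity.sum())
    pop = rng.poisson(intensity)
    pop = _rescale_to_total(pop.astype(np.float64), params.total_population)

    # Density for stratification: kernel-smoothed population, not the raw
    # Poisson draw, so labels follow the underlying settlement structure.
    density = intensity
    order = np.argsort(np.argsort(-density, kind="stable"), kind="stable")
    ranks = order / max(len(node_ids) - 1, 1)  # 0 = densest
    cuts = np.asarray(params.region_quantile_cuts)
    labels = [REGION_TYPES[int(np.searchsorted(cuts, r, side="left"))] for r in ranks]

    x_max = xy[:, 0].max() or 1.0
    stripe = np.minimum(
        (xy[:, 0] / (x_max + 1e-9) * params.n_admin_units).astype(int),
        params.n_admin_units - 1,
    )
    return [
        GridCell(
            cell_id=f"c{nid}",
            node_id=nid,
            population=int(p),
            region_type=lab,
            admin_unit=f"state_{st}",
        )
        for nid, p, lab, st in zip(node_ids, pop, labels, stripe)
    ]


def generate_facilities(
    params: SynthParams, cells: Sequence[GridCell]
) -> list[Facility]:
    """Sample facility sites proportional to cell population, draw linac counts.

    Sites are sampled without replacement with probability proportional to
    population (uniform if the scenario has zero population); linac counts
    are i.i.d. from ``linac_pmf``.  Deterministic given seed.
    """
    params.validate()
    if params.n_facilities > len(cells):
        raise ScenarioValidationError(
            f"n_facilities={params.n_facilities} exceeds number of cells ({len(cells)})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    cells = sorted(cells, key=lambda c: c.cell_id)
    pop = np.array([c.population for c in cells], dtype=np.float64)
    if pop.sum() > 0:
        p = pop / pop.sum()
    else:
        p = np.full(len(cells), 1.0 / len(cells))
    idx = rng.choice(len(cells), size=params.n_facilities, replace=False, p=p)
    idx = np.sort(idx)
    counts = sorted(params.linac_pmf)
    masses = np.array([params.linac_pmf[k] for k in counts])
    linacs = rng.choice(counts, size=params.n_facilities, p=masses)
    return [
        Facility(
            facility_id=f"f{k:03d}",
            node_id=cells[i].node_id,
            linacs=int(m),
            name=f"ROC {k:03d}",
            admin_unit=cells[i].admin_unit,
        )
        for k, (i, m) in enumerate(zip(idx, linacs))
    ]


def generate_scenario(params: SynthParams) -> Scenario:
    """Bundle network, population and facility generation into one scenario."""
    network = generate_network(params)
    cells = generate_population(params, network)
    facilities = generate_facilities(params, cells)
    scenario = Scenario(
        network=network,
        cells=cells,
        facilities=facilities,
        meta={"generator": "rednakit.scenario", "params": dataclasses.asdict(params)},
    )
    scenario.meta["params"]["linac_pmf"] = {
        str(k): v for k, v in params.linac_pmf.items()
    }
    scenario.validate()
    return scenario
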