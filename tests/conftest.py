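from __future__ import annotations

import numpy as np
import pytest

from rednakit.network import RoadNetwork, cost_matrix, rank_facilities
from rednakit.scenario import Facility, GridCell, Scenario, SynthParams, generate_scenario


def random_network(rng: np.random.Generator, n_max: int = 8, oneway_p: float = 0.2) -> RoadNetwork:
    """Small random road graph for oracle cross-checks (may be disconnected)."""
    n = int(rng.integers(2, n_max + 1))
    nodes = {f"v{i}": (float(i), 0.0) for i in range(n)}
    ids = sorted(nodes)
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.45:
                length = float(rng.uniform(200, 5000))
                speed = float(rng.choice([30.0, 50.0, 80.0, 120.0]))
                edges[(ids[i], ids[j])] = (length, speed, bool(rng.random() < oneway_p))
    return RoadNetwork(nodes=nodes, edges=edges)


def _toy() -> Scenario:
    # 8 nodes on a path-with-shortcuts; weights chosen so the fastest and
    # shortest routes differ for several node pairs.
    nodes = {f"v{i}": (float(i * 1000), 0.0) for i in range(8)}
    edges = {
        ("v0", "v1"): (1000.0, 50.0, False),
        ("v1", "v2"): (1500.0, 30.0, False),
        ("v2", "v3"): (800.0, 50.0, False),
        ("v3", "v4"): (1200.0, 80.0, False),
        ("v4", "v5"): (900.0, 50.0, False),
        ("v5", "v6"): (1100.0, 30.0, False),
        ("v6", "v7"): (1000.0, 50.0, False),
        ("v0", "v3"): (4000.0, 120.0, False),  # long but fast shortcut
        ("v2", "v5"): (2600.0, 100.0, False),
        ("v1", "v6"): (7000.0, 120.0, False),
    }
    network = RoadNetwork(nodes=nodes, edges=edges)
    cells = [
        GridCell(f"c{i}", f"v{i}", pop, "RS74", "state_0")
        for i, pop in enumerate([120, 80, 300, 50, 40, 260, 90, 150])
    ]
    facilities = [
        Facility("fA", "v2", linacs=2, name="A", admin_unit="state_0"),
        Facility("fB", "v6", linacs=1, name="B", admin_unit="state_0"),
    ]
    sc = Scenario(network=network, cells=cells, facilities=facilities)
    sc.validate()
    return sc


@pytest.fixture(scope="session")
def toy_scenario() -> Scenario:
    return _toy()


@pytest.fixture(scope="session")
def toy_matrix(toy_scenario):
    return cost_matrix(toy_scenario)


@pytest.fixture(scope="session")
def small_params() -> SynthParams:
    return SynthParams(
        lattice_n=12, total_population=400_000, n_urban_centers=2,
        n_facilities=6, seed=11,
    )


@pytest.fixture(scope="session")
def small_scenario(small_params):
    return generate_scenario(small_params)


@pytest.fixture(scope="session")
def small_matrix(small_scenario):
    return cost_matrix(small_scenario)


@pytest.fixture(scope="session")
def small_ranks(small_matrix):
    return rank_facilities(small_matrix, "time")
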