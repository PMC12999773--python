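"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: shortest costs are
found by exhaustive simple-path enumeration, weighted statistics by a plain
sort-and-scan loop.
"""

from __future__ import annotations

import math

from rednakit.network import RoadNetwork, edge_travel_time


def directed_adjacency(network: RoadNetwork) -> dict[str, list[tuple[str, float, float]]]:
    """node -> [(neighbor, time_min, dist_km)] honouring oneway flags."""
    adj: dict[str, list[tuple[str, float, float]]] = {n: [] for n in network.nodes}
    for (u, v), (length_m, speed_kmh, oneway) in network.edges.items():
        t = edge_travel_time(length_m, speed_kmh)
        d = length_m / 1000.0
        adj[u].append((v, t, d))
        if not oneway:
            adj[v].append((u, t, d))
    return adj


def enumerate_path_costs(
    network: RoadNetwork, source: str, target: str
) -> list[tuple[float, float]]:
    """(time_min, dist_km) of every simple path source -> target."""
    adj = directed_adjacency(network)
    out: list[tuple[float, float]] = []

    def dfs(node: str, visited: set[str], t: float, d: float) -> None:
        if node == target:
            out.append((t, d))
            return
        for nxt, et, ed in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, visited, t + et, d + ed)
                visited.remove(nxt)

    dfs(source, {source}, 0.0, 0.0)
    return out


def brute_force_best(
    network: RoadNetwork, source: str, target: str, weight: str
) -> tuple[float, set[float]]:
    """Minimum cost under ``weight`` and the set of companion values of all
    optimal simple paths; (inf, {inf}) when unreachable."""
    paths = enumerate_path_costs(network, source, target)
    if not paths:
        return math.inf, {math.inf}
    key = 0 if weight == "time" else 1
    best = min(p[key] for p in paths)
    companions = {p[1 - key] for p in paths if math.isclose(p[key], best)}
    return best, companions


def weighted_stat_scan(values, weights, which: str) -> float:
    """Plain-loop weighted mean / lower inverse-CDF quantile."""
    pairs = sorted(zip(values, weights), key=lambda p: p[0])
    total = sum(w for _, w in pairs)
    assert total > 0
    if which == "mean":
        return sum(v * w for v, w in pairs) / total
    q = {"median": 0.5, "p95": 0.95}[which]
    cum = 0.0
    for v, w in pairs:
        cum += w
        if cum / total >= q:
            return v
    return pairs[-1][0]
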