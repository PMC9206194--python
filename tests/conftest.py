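import numpy as np
import pandas as pd
import pytest

from txaccess.calibrated import calibrated_rosters, calibrated_tracts
from txaccess.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic scenario shared by read-only tests."""
    cfg = ScenarioConfig(seed=11, n_states=12, n_tracts_per_state=40, duplicate_rate=0.03)
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def calibrated():
    """Study-calibrated roster pair + law table + tract access table."""
    r2018, r2020, laws = calibrated_rosters()
    tracts = calibrated_tracts()
    return {"r2018": r2018, "r2020": r2020, "laws": laws, "tracts": tracts}


def random_connected_graph(rng, n_nodes, n_extra_edges, max_minutes=20.0):
    """Random connected weighted graph: a random spanning tree plus extras.

    Returns (nodes, edges) suitable for RoadNetwork; node coordinates are
    spread out so every node is its own nearest snap target.
    """
    nodes = {i: (float(i * 7 % (3 * n_nodes)), float(i * 13 % (5 * n_nodes))) for i in range(n_nodes)}
    edges = []
    order = rng.permutation(n_nodes)
    for i in range(1, n_nodes):
        u, v = int(order[i]), int(order[rng.integers(0, i)])
        edges.append((u, v, float(rng.uniform(0.5, max_minutes))))
    for _ in range(n_extra_edges):
        u, v = rng.integers(0, n_nodes, 2)
        if u != v:
            edges.append((int(u), int(v), float(rng.uniform(0.5, max_minutes))))
    return nodes, edges


def enumerate_min_path_minutes(edges, n_nodes, source, target):
    """Independent oracle: exhaustive enumeration of simple paths by DFS."""
    adj = {i: [] for i in range(n_nodes)}
    for u, v, w in edges:
        best = adj[u]
        adj[u].append((v, w))
        adj[v].append((u, w))
    best = [np.inf]

    def dfs(node, cost, visited):
        if cost >= best[0]:
            return
        if node == target:
            best[0] = cost
            return
        for nxt, w in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, cost + w, visited)
                visited.remove(nxt)

    dfs(source, 0.0, {source})
    return best[0]
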