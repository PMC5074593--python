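"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

import dynapath as dp
from dynapath.model import ROLE_CA, Node, NodeModel
from dynapath.network import DynamicNetwork


# ---------------------------------------------------------------------------
# builders


def point_node_model(n: int, chain_id: str = "A", resnum_start: int = 1) -> NodeModel:
    """n single-atom nodes on one chain (atom index == node id)."""
    return NodeModel(
        [
            Node(i, chain_id, resnum_start + i, "ALA", ROLE_CA, (i,), i)
            for i in range(n)
        ],
        n_atoms=n,
    )


def net_from_corr_edges(edges, n_nodes=None) -> DynamicNetwork:
    """DynamicNetwork from (u, v, corr) triples; weight = -ln|corr|."""
    g = nx.Graph()
    if n_nodes is not None:
        g.add_nodes_from(range(n_nodes))
    for u, v, c in edges:
        g.add_edge(
            u, v, weight=float(-np.log(abs(c))), corr=float(c), abscorr=abs(float(c)),
            contact_fraction=1.0,
        )
    return DynamicNetwork(g)


def random_network(seed: int, n_max: int = 9, p: float = 0.4) -> DynamicNetwork:
    """Seeded random correlation-weighted graph with 3..n_max nodes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((i, j, float(rng.uniform(0.05, 0.999))))
    return net_from_corr_edges(edges, n_nodes=n)


# ---------------------------------------------------------------------------
# brute-force path oracles (independent of the package's algorithms)


def enumerate_simple_paths(network: DynamicNetwork, s: int, t: int):
    """All simple s→t paths as (raw_length, node tuple), by naive DFS."""
    g = network.graph
    out = []

    def dfs(u, path, length):
        if u == t:
            out.append((length, tuple(path)))
            return
        for v in g.neighbors(u):
            if v in path:
                continue
            dfs(v, path + [v], length + g.edges[u, v]["weight"])

    dfs(s, [s], 0.0)
    return out


def brute_shortest(network: DynamicNetwork, s: int, t: int):
    paths = enumerate_simple_paths(network, s, t)
    return min((p[0] for p in paths), default=np.inf)


# ---------------------------------------------------------------------------
# shared expensive fixtures (planted benchmark, sampled once)


@pytest.fixture(scope="session")
def planted_model():
    return dp.make_planted_model(n_per_block=10)


@pytest.fixture(scope="session")
def planted_traj(planted_model):
    return dp.sample_trajectory(planted_model, 20000, seed=2024)


@pytest.fixture(scope="session")
def planted_network(planted_model, planted_traj):
    cm = dp.compute_dccm(planted_traj, planted_model.node_model)
    ct = dp.compute_contacts(planted_traj, planted_model.node_model)
    return dp.build_network(ct, cm, planted_model.node_model)
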