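"""Optimal and suboptimal communication pathways between anchored sites.

The optimal path between two nodes is the minimum total-weight simple
path on the dynamic network (weights −ln|C_ij| ≥ 0), computed here with a
Floyd–Warshall all-pairs pass.  Suboptimal paths are *all* simple paths
whose length lies within a fixed offset of the optimum, enumerated by a
bounded depth-first search that uses exact distances-to-target as an
admissible pruning bound — the enumeration is exhaustive within the
bound, not sampled.

Reported path statistics follow the conventions of the published MutS
path tables:

* ``N``   — number of hops (edges) along the path;
* ``W``   — overall weight, 100 × Σ_k (−ln|c_k|) over consecutive pairs;
* ``min`` — the minimum pairwise correlation |c_k| along the path.

A path is classified *effective* when min ≥ 0.7: a route with even one
poorly coupled link is not considered a usable communication channel,
however light its total weight.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import NodeModel
from .network import DynamicNetwork

_EPS = 1e-9
EFFECTIVE_MIN_CORR = 0.7


@dataclass(frozen=True)
class Path:
    """A simple path with the (N, W, min) statistics."""

    nodes: tuple[int, ...]
    n_hops: int
    weight100: float  # W, on the ×100 reported scale
    min_corr: float
    edge_corrs: tuple[float, ...] = ()

    @property
    def raw_length(self) -> float:
        return self.weight100 / 100.0

    def w_rounded(self) -> int:
        return int(round(self.weight100))


@dataclass
class AllPairsPaths:
    """Distances + successor structure from a Floyd–Warshall pass."""

    dist: np.ndarray  # (n, n); np.inf marks unreachable pairs
    nxt: np.ndarray  # successor matrix; -1 marks no route

    def path_nodes(self, source: int, sink: int) -> list[int] | None:
        if source == sink:
            return [source]
        if self.nxt[source, sink] < 0:
            return None
        out = [source]
        cur = source
        while cur != sink:
            cur = int(self.nxt[cur, sink])
            out.append(cur)
        return out


def all_pairs_optimal(network: DynamicNetwork) -> AllPairsPaths:
    """Exact all-pairs shortest paths (Floyd–Warshall).

    Weights are non-negative by construction.  Updates are strict
    improvements applied with intermediate nodes in increasing order, so
    the successor matrix — and hence every reconstructed path — is
    deterministic for a fixed input.
    """
    n = network.n_nodes
    dist = np.full((n, n), np.inf)
    nxt = np.full((n, n), -1, dtype=np.int64)
    np.fill_diagonal(dist, 0.0)
    for u, v, data in network.graph.edges(data=True):
        w = float(data["weight"])
        if w < dist[u, v]:
            dist[u, v] = dist[v, u] = w
            nxt[u, v] = v
            nxt[v, u] = u
    for k in range(n):
        alt = dist[:, k, None] + dist[None, k, :]
        improve = alt < dist - _EPS
        np.fill_diagonal(improve, False)
        if improve.any():
            dist = np.where(improve, alt, dist)
            rows = np.nonzero(improve.any(axis=1))[0]
            for i in rows:
                cols = np.nonzero(improve[i])[0]
                nxt[i, cols] = nxt[i, k]
    return AllPairsPaths(dist, nxt)


def path_statistics(network: DynamicNetwork, nodes: Sequence[int]) -> Path:
    """(N, W, min) for an explicit node sequence; every edge must exist."""
    nodes = tuple(int(x) for x in nodes)
    if len(nodes) < 2:
        raise ValueError("a path needs at least 2 nodes")
    if len(set(nodes)) != len(nodes):
        raise ValueError("path revisits a node")
    corrs = []
    total = 0.0
    for u, v in zip(nodes, nodes[1:]):
        if not network.graph.has_edge(u, v):
            raise ValueError(f"edge {u}-{v} missing from the network")
        data = network.graph.edges[u, v]
        corrs.append(abs(float(data["corr"])))
        total += float(data["weight"])
    return Path(
        nodes=nodes,
        n_hops=len(nodes) - 1,
        weight100=100.0 * total,
        min_corr=min(corrs),
        edge_corrs=tuple(corrs),
    )


def optimal_path(
    network: DynamicNetwork,
    source: int,
    sink: int,
    all_pairs: AllPairsPaths | None = None,
) -> Path | None:
    """Minimum-weight simple path, or ``None`` when the pair is
    disconnected (a valid outcome, not an error)."""
    if source == sink:
        raise ValueError("source and sink must differ")
    ap = all_pairs if all_pairs is not None else all_pairs_optimal(network)
    nodes = ap.path_nodes(source, sink)
    if nodes is None:
        return None
    return path_statistics(network, nodes)


@dataclass
class EffectiveReport:
    effective: bool
    threshold: float
    limiting_edge: tuple[int, int]
    limiting_corr: float


def classify_effective(path: Path, threshold: float = EFFECTIVE_MIN_CORR) -> EffectiveReport:
    """Effective iff the weakest link has |c| >= threshold ("at least")."""
    k = int(np.argmin(path.edge_corrs))
    return EffectiveReport(
        effective=path.min_corr >= threshold,
        threshold=threshold,
        limiting_edge=(path.nodes[k], path.nodes[k + 1]),
        limiting_corr=path.min_corr,
    )


@dataclass
class PathEnsemble:
    """Optimal path + all simple paths within ``offset`` of it.

    ``offset`` is expressed on the ×100 reported-weight scale (an offset
    of 10 admits paths up to 0.10 above the optimum in raw −ln units).
    ``degeneracy`` — the ensemble size — measures how many near-equivalent
    routes exist; the per-edge traversal counts are the edge betweenness
    within the ensemble, and edges crossed by (nearly) all paths are the
    communication bottlenecks.
    """

    source: int
    sink: int
    offset: float
    optimal: Path
    suboptimals: list[Path]
    edge_counts: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def degeneracy(self) -> int:
        return len(self.suboptimals)


class EnsembleSizeError(RuntimeError):
    pass


def suboptimal_paths(
    network: DynamicNetwork,
    source: int,
    sink: int,
    offset: float,
    cap: int = 1_000_000,
) -> PathEnsemble | None:
    """All simple paths with W ≤ W_opt + offset (×100 scale).

    Returns ``None`` for a disconnected pair.  Raises
    :class:`EnsembleSizeError` when more than ``cap`` paths qualify —
    choose a smaller offset in that case.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if source == sink:
        raise ValueError("source and sink must differ")
    dist_to_sink = _dijkstra(network, sink)
    if not np.isfinite(dist_to_sink[source]):
        return None
    bound = dist_to_sink[source] + offset / 100.0
    adj: dict[int, list[tuple[int, float]]] = {
        u: sorted(
            (v, float(network.graph.edges[u, v]["weight"]))
            for v in network.graph.neighbors(u)
        )
        for u in network.graph.nodes
    }
    found: list[list[int]] = []
    on_path = {source}
    stack_path = [source]

    def dfs(u: int, length: float) -> None:
        if u == sink:
            found.append(list(stack_path))
            if len(found) > cap:
                raise EnsembleSizeError(
                    f"more than {cap} suboptimal paths within offset {offset}; "
                    "use a smaller offset or raise the cap"
                )
            return
        for v, w in adj[u]:
            if v in on_path:
                continue
            nl = length + w
            if nl + dist_to_sink[v] > bound + _EPS:
                continue
            on_path.add(v)
            stack_path.append(v)
            dfs(v, nl)
            stack_path.pop()
            on_path.remove(v)

    dfs(source, 0.0)
    paths = sorted(
        (path_statistics(network, p) for p in found),
        key=lambda p: (p.weight100, p.nodes),
    )
    counts: dict[tuple[int, int], int] = {}
    for p in paths:
        for u, v in zip(p.nodes, p.nodes[1:]):
            e = (min(u, v), max(u, v))
            counts[e] = counts.get(e, 0) + 1
    return PathEnsemble(
        source=source,
        sink=sink,
        offset=offset,
        optimal=paths[0],
        suboptimals=paths,
        edge_counts=counts,
    )


def _dijkstra(network: DynamicNetwork, source: int) -> np.ndarray:
    """Single-source distances (non-negative weights), used both as the
    admissible DFS bound and as an independent check on Floyd–Warshall."""
    n = network.n_nodes
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    pq: list[tuple[float, int]] = [(0.0, source)]
    done = np.zeros(n, dtype=bool)
    while pq:
        d, u = heapq.heappop(pq)
        if done[u]:
            continue
        done[u] = True
        for v in network.graph.neighbors(u):
            nd = d + float(network.graph.edges[u, v]["weight"])
            if nd < dist[v] - _EPS:
                dist[v] = nd
                heapq.heappush(pq, (nd, v))
    return dist


def path_ensemble_betweenness(
    ensemble: PathEnsemble,
) -> list[tuple[tuple[int, int], int]]:
    """Per-edge traversal counts, ranked (count desc, edge lexicographic).

    An edge crossed by every path of the ensemble is a bottleneck: there
    is no alternate route around it within the offset.
    """
    if not ensemble.suboptimals:
        raise ValueError("empty path ensemble")
    return sorted(ensemble.edge_counts.items(), key=lambda kv: (-kv[1], kv[0]))


def bottleneck_edges(ensemble: PathEnsemble) -> list[tuple[int, int]]:
    return [e for e, c in ensemble.edge_counts.items() if c == ensemble.degeneracy]


# ---------------------------------------------------------------------------
# anchor selection


@dataclass
class AnchorSpec:
    """A functional site (a set of atom coordinates) and the 10 Å shell of
    candidate anchor nodes around it."""

    site_coords: np.ndarray  # (m, 3) Å
    radius: float = 10.0
    candidates: tuple[int, ...] = ()


def candidate_nodes_near_site(
    node_model: NodeModel,
    reference_coords: np.ndarray,
    site_atoms: Sequence[int] | np.ndarray,
    radius: float = 10.0,
) -> list[int]:
    """Nodes with any member heavy atom within ``radius`` of any site atom
    on the designated reference frame.  Empty shells are an error —
    anchoring would be impossible."""
    site_atoms = np.asarray(site_atoms, dtype=int)
    if site_atoms.size == 0:
        raise ValueError("site atom set is empty")
    site_xyz = reference_coords[site_atoms]
    out: list[int] = []
    for node in node_model:
        ats = list(node.member_atoms)
        d = np.linalg.norm(
            reference_coords[ats][:, None, :] - site_xyz[None, :, :], axis=-1
        )
        if d.min() <= radius:
            out.append(node.node_id)
    if not out:
        raise ValueError(f"no nodes within {radius} Å of the site")
    return out


def select_anchor_pair(
    network: DynamicNetwork,
    set_a: Sequence[int],
    set_b: Sequence[int],
    all_pairs: AllPairsPaths | None = None,
) -> tuple[tuple[int, int], Path] | None:
    """The candidate pair with the shortest optimal path (ties broken by
    the lexicographically lowest node-id pair); ``None`` when every pair
    is disconnected."""
    if not set_a or not set_b:
        raise ValueError("candidate sets must be non-empty")
    ap = all_pairs if all_pairs is not None else all_pairs_optimal(network)
    best: tuple[float, tuple[int, int]] | None = None
    for a in sorted(set_a):
        for b in sorted(set_b):
            if a == b:
                continue
            d = ap.dist[a, b]
            if not np.isfinite(d):
                continue
            key = (float(d), (a, b))
            if best is None or key < best:
                best = key
    if best is None:
        return None
    (a, b) = best[1]
    path = optimal_path(network, a, b, all_pairs=ap)
    assert path is not None
    return (a, b), path
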