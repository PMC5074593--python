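"""Community structure of the dynamic network (Girvan–Newman).

Communities are groups of nodes more densely interconnected among
themselves than with the rest of the network; in an allosteric network
they typically correspond to (semi-)rigid structural domains, and the
sparse edges *between* communities are the candidate communication
bottlenecks.

The Girvan–Newman procedure iteratively removes the edge with the
highest edge betweenness (recomputed after every removal, with shortest
paths measured by the network's −ln|C| weights) and records the component
partition after each removal.  The returned partition is the one that
maximises weighted modularity along this dendrogram, with |C_ij| used as
the modularity strength weight (modularity expects an affinity, not a
distance).  Ties are broken deterministically: lexicographically smallest
edge on equal betweenness, fewest communities on equal modularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Sequence

import networkx as nx
import numpy as np

from .network import DynamicNetwork
from .paths import PathEnsemble


@dataclass
class CommunityPartition:
    labels: dict[int, int]  # node -> community id (0-based, by smallest member)
    n_communities: int
    modularity: float
    removal_order: list[tuple[int, int]] = field(default_factory=list)

    def communities(self) -> list[set[int]]:
        out: dict[int, set[int]] = {}
        for node, c in self.labels.items():
            out.setdefault(c, set()).add(node)
        return [out[k] for k in sorted(out)]

    def to_tsv(self, path: str | FilePath, network: DynamicNetwork | None = None) -> None:
        import pandas as pd

        rows = [
            {
                "node": node,
                "label": network.label(node) if network else str(node),
                "community": c,
            }
            for node, c in sorted(self.labels.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _canonical_labels(components: Sequence[set[int]]) -> dict[int, int]:
    comps = sorted(components, key=min)
    return {node: k for k, comp in enumerate(comps) for node in comp}


def _modularity(graph: nx.Graph, components: Sequence[set[int]], weight: str) -> float:
    if graph.number_of_edges() == 0:
        return 0.0
    return float(
        nx.algorithms.community.modularity(graph, components, weight=weight)
    )


def girvan_newman(
    network: DynamicNetwork,
    distance_weight: str = "weight",
    strength_weight: str = "abscorr",
) -> CommunityPartition:
    """Max-modularity partition along the Girvan–Newman dendrogram.

    An edgeless graph yields the singleton partition with modularity 0.
    """
    g0 = network.graph
    if g0.number_of_edges() == 0:
        labels = _canonical_labels([{n} for n in g0.nodes])
        return CommunityPartition(labels, len(labels), 0.0, [])

    work = g0.copy()
    removal_order: list[tuple[int, int]] = []
    best_components: list[set[int]] | None = None
    best_mod = -np.inf
    best_ncomm = 0

    def consider(components: list[set[int]]) -> None:
        nonlocal best_components, best_mod, best_ncomm
        q = _modularity(g0, components, strength_weight)
        if q > best_mod + 1e-12 or (
            abs(q - best_mod) <= 1e-12 and len(components) < best_ncomm
        ):
            best_mod = q
            best_components = [set(c) for c in components]
            best_ncomm = len(components)

    consider([set(c) for c in nx.connected_components(work)])
    while work.number_of_edges() > 0:
        bc = nx.edge_betweenness_centrality(work, weight=distance_weight)
        # deterministic: max betweenness, then lexicographically smallest edge
        edge = min(
            bc, key=lambda e: (-bc[e], (min(e), max(e)))
        )
        edge = (min(edge), max(edge))
        work.remove_edge(*edge)
        removal_order.append(edge)
        consider([set(c) for c in nx.connected_components(work)])

    assert best_components is not None
    labels = _canonical_labels(best_components)
    return CommunityPartition(labels, len(best_components), float(best_mod), removal_order)


@dataclass
class InterCommunityEdge:
    edge: tuple[int, int]
    communities: tuple[int, int]
    corr: float
    weight: float
    ensemble_betweenness: int


def critical_intercommunity_edges(
    partition: CommunityPartition,
    network: DynamicNetwork,
    ensembles: Sequence[PathEnsemble] = (),
) -> list[InterCommunityEdge]:
    """Edges whose endpoints lie in different communities, ranked by how
    many (sub)optimal pathway-ensemble paths traverse them.

    These are the critical inter-community edges: removal or perturbation
    of a highly travelled one would re-route or silence the communication
    between the domains it joins.
    """
    counts: dict[tuple[int, int], int] = {}
    for ens in ensembles:
        for e, c in ens.edge_counts.items():
            counts[e] = counts.get(e, 0) + c
    out: list[InterCommunityEdge] = []
    for u, v, data in network.graph.edges(data=True):
        cu, cv = partition.labels[u], partition.labels[v]
        if cu == cv:
            continue
        e = (min(u, v), max(u, v))
        out.append(
            InterCommunityEdge(
                edge=e,
                communities=(min(cu, cv), max(cu, cv)),
                corr=float(data["corr"]),
                weight=float(data["weight"]),
                ensemble_betweenness=counts.get(e, 0),
            )
        )
    return sorted(out, key=lambda x: (-x.ensemble_betweenness, x.edge))
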