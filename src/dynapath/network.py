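"""Contact-filtered, correlation-weighted dynamic network construction.

Two nodes are in contact when the minimum distance between their member
heavy atoms is within 4.5 Å in more than 75% of the pooled trajectory
frames; sequence-adjacent residues of the same chain and the two nodes of
one nucleotide are excluded as trivial covalent neighbours.  Each contact
becomes an undirected edge weighted

    w_ij = -ln |C_ij|

so strongly correlated pairs are "short" and shortest paths follow chains
of high pairwise correlation.  The natural logarithm is used; the signed
correlation is kept on every edge for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path as FilePath

import networkx as nx
import numpy as np

from .correlation import CorrelationMatrix
from .model import NodeModel, TrajectoryEnsemble

CONTACT_CUTOFF = 4.5  # Å
CONTACT_FRACTION = 0.75  # "more than 75%" -> strictly greater
CORRELATION_FLOOR = 1e-6  # |C| floored before the log so weights stay finite


@dataclass
class ContactMatrix:
    contact: np.ndarray  # boolean n×n
    fraction: np.ndarray  # per-pair fraction of frames within cutoff
    cutoff: float
    fraction_threshold: float
    excluded: np.ndarray  # boolean mask of neighbour-excluded pairs
    mode: str

    @property
    def n(self) -> int:
        return self.contact.shape[0]

    def pairs(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n, k=1)
        mask = self.contact[iu]
        return [
            (int(i), int(j)) for i, j in zip(iu[0][mask], iu[1][mask])
        ]


def compute_contacts(
    traj: TrajectoryEnsemble,
    node_model: NodeModel,
    cutoff: float = CONTACT_CUTOFF,
    fraction: float = CONTACT_FRACTION,
    mode: str = "heavy-atom",
) -> ContactMatrix:
    """Occupancy-filtered contact map over all pooled frames.

    ``mode='heavy-atom'`` (default) uses the minimum distance between the
    member heavy atoms of the two nodes; ``mode='node-point'`` uses the
    representative-atom distance (sensitivity-check alternative).
    Distances are frame-internal, so no superposition is required.
    """
    if mode not in ("heavy-atom", "node-point"):
        raise ValueError(f"unknown contact mode {mode!r}")
    n = len(node_model)
    for node in node_model:
        if not node.member_atoms:
            raise ValueError(f"node {node.node_id} ({node.label}) has no member atoms")
    F = traj.n_frames
    frac = np.zeros((n, n))
    excluded = np.zeros((n, n), dtype=bool)
    for i, j in node_model.neighbor_pairs():
        excluded[i, j] = excluded[j, i] = True

    rep = node_model.representative_atoms
    rep_xyz = traj.coords[:, rep, :]
    if mode == "node-point":
        d = np.linalg.norm(rep_xyz[:, :, None, :] - rep_xyz[:, None, :, :], axis=-1)
        frac = (d <= cutoff).mean(axis=0)
    else:
        # per-node spread around its representative atom (bounding radius)
        radius = np.zeros(n)
        for node in node_model:
            ats = list(node.member_atoms)
            dd = np.linalg.norm(
                traj.coords[:, ats, :] - traj.coords[:, [node.representative_atom], :],
                axis=-1,
            )
            radius[node.node_id] = dd.max() if dd.size else 0.0
        rep_d = np.linalg.norm(
            rep_xyz[:, :, None, :] - rep_xyz[:, None, :, :], axis=-1
        )
        for i in range(n):
            ai = list(node_model[i].member_atoms)
            for j in range(i + 1, n):
                if excluded[i, j]:
                    continue
                if len(ai) == 1 and len(node_model[j].member_atoms) == 1:
                    frac[i, j] = frac[j, i] = (rep_d[:, i, j] <= cutoff).mean()
                    continue
                # min atom distance >= rep distance - radii, so frames
                # beyond that bound cannot contribute to the fraction
                candidate = np.flatnonzero(
                    rep_d[:, i, j] <= cutoff + radius[i] + radius[j]
                )
                if candidate.size == 0:
                    continue
                aj = list(node_model[j].member_atoms)
                diff = (
                    traj.coords[np.ix_(candidate, ai)][:, :, None, :]
                    - traj.coords[np.ix_(candidate, aj)][:, None, :, :]
                )
                within = np.linalg.norm(diff, axis=-1).min(axis=(1, 2)) <= cutoff
                frac[i, j] = frac[j, i] = within.sum() / F
    np.fill_diagonal(frac, 0.0)
    contact = (frac > fraction) & ~excluded
    np.fill_diagonal(contact, False)
    contact &= contact.T
    return ContactMatrix(contact, frac, cutoff, fraction, excluded, mode)


class DynamicNetwork:
    """Thin wrapper over an undirected weighted :class:`networkx.Graph`.

    Edge attributes: ``weight`` (−ln|C|), ``corr`` (signed C), ``abscorr``
    and ``contact_fraction``.  The graph may be disconnected; path queries
    must treat that as a valid outcome.
    """

    def __init__(self, graph: nx.Graph, node_model: NodeModel | None = None):
        self.graph = graph
        self.node_model = node_model

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, u: int, v: int) -> float:
        return float(self.graph.edges[u, v]["weight"])

    def edge_corr(self, u: int, v: int) -> float:
        return float(self.graph.edges[u, v]["corr"])

    def label(self, node: int) -> str:
        if self.node_model is not None:
            return self.node_model[node].label
        return str(node)

    def to_edge_tsv(self, path: str | FilePath) -> None:
        import pandas as pd

        rows = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            rows.append(
                {
                    "node_i": u,
                    "node_j": v,
                    "label_i": self.label(u),
                    "label_j": self.label(v),
                    "corr": data["corr"],
                    "abs_corr": data["abscorr"],
                    "weight": data["weight"],
                    "contact_fraction": data.get("contact_fraction", np.nan),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_edge_tsv(cls, path: str | FilePath) -> "DynamicNetwork":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(
                int(row.node_i),
                int(row.node_j),
                weight=float(row.weight),
                corr=float(row.corr),
                abscorr=float(row.abs_corr),
                contact_fraction=float(row.contact_fraction),
            )
        return cls(g)


def correlation_to_weight(c: float, floor: float = CORRELATION_FLOOR) -> float:
    """w = −ln|c| with |c| floored so the weight is finite and ≥ 0."""
    return float(-np.log(min(max(abs(c), floor), 1.0)))


def build_network(
    contacts: ContactMatrix,
    dccm: CorrelationMatrix,
    node_model: NodeModel | None = None,
) -> DynamicNetwork:
    """Edges for every contact, weighted by −ln|C_ij| of the two end nodes."""
    if contacts.n != dccm.n:
        raise ValueError(
            f"dimension mismatch: contacts for {contacts.n} nodes, "
            f"DCCM for {dccm.n}"
        )
    degenerate = set(dccm.degenerate_nodes)
    g = nx.Graph()
    g.add_nodes_from(range(contacts.n))
    for i, j in contacts.pairs():
        if i in degenerate or j in degenerate:
            raise ValueError(
                f"contact {i}-{j} involves a zero-variance node; its "
                "correlation is undefined"
            )
        c = float(dccm.C[i, j])
        g.add_edge(
            i,
            j,
            weight=correlation_to_weight(c),
            corr=c,
            abscorr=abs(c),
            contact_fraction=float(contacts.fraction[i, j]),
        )
    if node_model is not None:
        for node in node_model:
            g.nodes[node.node_id]["label"] = node.label
            g.nodes[node.node_id]["role"] = node.role
    return DynamicNetwork(g, node_model)
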