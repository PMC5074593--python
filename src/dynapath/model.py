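"""Core in-memory containers shared across the pipeline.

The coarse-grained representation follows the standard dynamical-network
convention for protein/nucleic systems: one node per amino-acid residue
(placed at the Cα) and two nodes per nucleotide — one on the base side
(N1 for pyrimidines, N9 for purines) and one on the phosphate side
(Pα for free nucleotides such as ATP/ADP, P for a nucleic-acid backbone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: node roles
ROLE_CA = "amino-acid-Ca"
ROLE_BASE = "nucleotide-base"
ROLE_PHOSPHATE = "nucleotide-phosphate"

_VALID_ROLES = frozenset({ROLE_CA, ROLE_BASE, ROLE_PHOSPHATE})


@dataclass(frozen=True)
class Node:
    """A single network node.

    ``node_id`` is the 0-based internal index; ``resnum`` is reported exactly
    as authored in the source structure (1-based in conventional PDB files)
    so that residue labels like ``A:36`` match the literature numbering.
    """

    node_id: int
    chain_id: str
    resnum: int
    resname: str
    role: str
    member_atoms: tuple[int, ...]
    representative_atom: int

    def __post_init__(self) -> None:
        if self.role not in _VALID_ROLES:
            raise ValueError(f"unknown node role {self.role!r}")
        if self.representative_atom not in self.member_atoms:
            raise ValueError(
                f"representative atom {self.representative_atom} of node "
                f"{self.chain_id}:{self.resnum} is not a member atom"
            )

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.resnum}"


class NodeModel:
    """Ordered collection of nodes with chain/residue bookkeeping."""

    def __init__(self, nodes: Sequence[Node], n_atoms: int | None = None):
        nodes = list(nodes)
        for i, node in enumerate(nodes):
            if node.node_id != i:
                raise ValueError(
                    f"node ids must be contiguous from 0; got {node.node_id} at {i}"
                )
        seen: dict[int, int] = {}
        for node in nodes:
            for a in node.member_atoms:
                if a in seen:
                    raise ValueError(
                        f"atom {a} assigned to both node {seen[a]} and node {node.node_id}"
                    )
                seen[a] = node.node_id
        self._nodes = nodes
        self.n_atoms = (
            n_atoms if n_atoms is not None else (max(seen) + 1 if seen else 0)
        )

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[Node]:
        return iter(self._nodes)

    def __getitem__(self, node_id: int) -> Node:
        return self._nodes[node_id]

    @property
    def nodes(self) -> list[Node]:
        return list(self._nodes)

    @property
    def representative_atoms(self) -> np.ndarray:
        return np.array([n.representative_atom for n in self._nodes], dtype=int)

    def labels(self) -> list[str]:
        return [n.label for n in self._nodes]

    def find(self, chain_id: str, resnum: int, role: str | None = None) -> Node:
        for node in self._nodes:
            if node.chain_id == chain_id and node.resnum == resnum:
                if role is None or node.role == role:
                    return node
        raise KeyError(f"no node {chain_id}:{resnum} (role={role})")

    def neighbor_pairs(self) -> set[tuple[int, int]]:
        """Pairs excluded from the contact graph as trivial covalent neighbours.

        Sequence-adjacent residues of the same chain (|Δresnum| = 1) and the
        two nodes representing the same nucleotide would be correlated for
        purely covalent reasons and would otherwise dominate every path.
        """
        pairs: set[tuple[int, int]] = set()
        for i, a in enumerate(self._nodes):
            for b in self._nodes[i + 1 :]:
                if a.chain_id != b.chain_id:
                    continue
                if abs(a.resnum - b.resnum) == 1 or a.resnum == b.resnum:
                    pairs.add((a.node_id, b.node_id))
        return pairs


@dataclass
class TrajectoryEnsemble:
    """Frames × atoms × 3 Cartesian coordinates in Å plus sampling metadata."""

    coords: np.ndarray
    frame_interval_ps: float = 1.0
    superposed: bool = False
    source: str = "in-memory"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory contains non-finite coordinates")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_ps(self) -> float:
        return self.n_frames * self.frame_interval_ps

    def window(self, n_frames: int, label: str | None = None) -> "TrajectoryEnsemble":
        """Cumulative prefix of the trajectory (first ``n_frames`` frames)."""
        if not 0 < n_frames <= self.n_frames:
            raise ValueError(f"window of {n_frames} frames out of range")
        src = label or f"{self.source}[:{n_frames}]"
        return TrajectoryEnsemble(
            self.coords[:n_frames], self.frame_interval_ps, self.superposed, src
        )
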