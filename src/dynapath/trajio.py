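"""Structure/trajectory reading, node-model construction and superposition.

File parsing is delegated to mdtraj (PDB topologies, DCD/XTC/and other
standard coordinate formats); this module owns the coarse-graining rules:
which atoms define a node, how nucleotides are split into a base-side and
a phosphate-side node, and the superposition protocol applied before
displacement correlations are computed.

Coordinates are handled in Å throughout (mdtraj's nm are converted on
load/save).  Residue numbers are reported exactly as authored in the
source file; internal node ids are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path as FilePath
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model import (
    ROLE_BASE,
    ROLE_CA,
    ROLE_PHOSPHATE,
    Node,
    NodeModel,
    TrajectoryEnsemble,
)

_PURINES = {"A", "G", "DA", "DG", "ATP", "ADP", "GTP", "GDP", "AMP", "GMP"}
_PYRIMIDINES = {"C", "T", "U", "DC", "DT", "DU", "CTP", "UTP", "TTP"}
_NUCLEOTIDES = _PURINES | _PYRIMIDINES
#: free (non-polymeric) nucleotides carry their alpha-phosphate as PA
_FREE_NUCLEOTIDES = {"ATP", "ADP", "GTP", "GDP", "AMP", "GMP", "CTP", "UTP", "TTP"}

#: base-side atoms of a nucleotide node: ring system, exocyclic substituents
#: and the glycosidic C1'; everything else (phosphates + sugar) goes to the
#: phosphate-side node.
_BASE_SIDE = {
    "N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
    "N2", "N4", "N6", "O2", "O4", "O6", "C5M", "C7",
    "C1'", "C1*",
}

_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL", "MSE",
}


def _is_hydrogen(atom_name: str, element: str | None) -> bool:
    if element:
        return element.upper() == "H"
    return atom_name.lstrip("0123456789").startswith("H")


def load_topology(structure_file: str | FilePath) -> NodeModel:
    """Build the coarse-grained node model from a PDB structure.

    One node per amino-acid residue at the Cα; two nodes per nucleotide —
    base side at N9 (purines) or N1 (pyrimidines), phosphate side at Pα
    (free nucleotides like ATP/ADP) or P (nucleic-acid backbone).  Waters,
    ions and unrecognised residues are skipped with a warning.  A residue
    lacking its representative atom is an error naming the residue.
    """
    import mdtraj as md

    top = md.load_topology(str(structure_file))
    nodes: list[Node] = []
    nid = 0
    for chain in top.chains:
        cid = chain.chain_id if chain.chain_id and chain.chain_id.strip() else str(
            chain.index
        )
        for res in chain.residues:
            resname = res.name.upper()
            heavy = [
                a for a in res.atoms if not _is_hydrogen(a.name, getattr(a.element, "symbol", None))
            ]
            names = {a.name.upper(): a.index for a in heavy}
            if resname in _AMINO3 or (res.is_protein and "CA" in names):
                if "CA" not in names:
                    raise ValueError(
                        f"residue {cid}:{resname}{res.resSeq} lacks a Cα atom"
                    )
                nodes.append(
                    Node(
                        node_id=nid,
                        chain_id=cid,
                        resnum=res.resSeq,
                        resname=resname,
                        role=ROLE_CA,
                        member_atoms=tuple(a.index for a in heavy),
                        representative_atom=names["CA"],
                    )
                )
                nid += 1
            elif resname in _NUCLEOTIDES:
                base_rep = "N9" if resname in _PURINES else "N1"
                phos_rep = "PA" if resname in _FREE_NUCLEOTIDES else "P"
                for rep in (base_rep, phos_rep):
                    if rep not in names:
                        raise ValueError(
                            f"nucleotide {cid}:{resname}{res.resSeq} lacks "
                            f"representative atom {rep}"
                        )
                base_atoms = tuple(
                    a.index for a in heavy if a.name.upper() in _BASE_SIDE
                )
                phos_atoms = tuple(
                    a.index for a in heavy if a.name.upper() not in _BASE_SIDE
                )
                nodes.append(
                    Node(nid, cid, res.resSeq, resname, ROLE_BASE, base_atoms,
                         names[base_rep])
                )
                nodes.append(
                    Node(nid + 1, cid, res.resSeq, resname, ROLE_PHOSPHATE,
                         phos_atoms, names[phos_rep])
                )
                nid += 2
            else:
                warnings.warn(
                    f"skipping unrecognised residue {cid}:{resname}{res.resSeq}",
                    stacklevel=2,
                )
    return NodeModel(nodes, n_atoms=top.n_atoms)


def load_trajectory(
    files: str | FilePath | Sequence[str | FilePath],
    node_model: NodeModel,
    topology: str | FilePath | None = None,
    frame_interval_ps: float = 1.0,
) -> TrajectoryEnsemble:
    """Load and concatenate coordinate files (in the given order).

    ``topology`` is required for formats that do not carry their own
    (DCD/XTC); the atom count must match the node model.
    """
    import mdtraj as md

    if isinstance(files, (str, FilePath)):
        files = [files]
    parts = []
    for f in files:
        kwargs = {"top": str(topology)} if topology is not None else {}
        parts.append(md.load(str(f), **kwargs))
    traj = parts[0] if len(parts) == 1 else parts[0].join(parts[1:])
    if traj.n_frames == 0:
        raise ValueError("trajectory contains zero frames")
    if traj.n_atoms != node_model.n_atoms:
        raise ValueError(
            f"atom count mismatch: trajectory has {traj.n_atoms}, "
            f"node model expects {node_model.n_atoms}"
        )
    return TrajectoryEnsemble(
        np.asarray(traj.xyz, dtype=float) * 10.0,  # nm -> Å
        frame_interval_ps=frame_interval_ps,
        superposed=False,
        source=", ".join(str(f) for f in files),
    )


def superpose(
    traj: TrajectoryEnsemble,
    selection: Sequence[int] | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> TrajectoryEnsemble:
    """Least-squares rigid-body fit of every frame to the ensemble mean.

    The fit is iterated (fit → recompute mean → fit, at least twice) until
    the mean reference structure stops changing, so the reference is
    self-consistent and the operation is idempotent; rotations are proper
    (determinant +1).  ``selection`` is the atom-index set used for the
    fit (default: all atoms); the transform is applied to all atoms.
    """
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, int)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 selection atoms")
    coords = traj.coords.copy()
    prev_ref = None
    for _ in range(max_iter):
        ref = coords[:, sel].mean(axis=0)
        if prev_ref is not None and np.abs(ref - prev_ref).max() < tol:
            break
        prev_ref = ref
        ref_c = ref - ref.mean(axis=0)
        for f in range(coords.shape[0]):
            mob = coords[f, sel]
            cen = mob.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_c, mob - cen)
            coords[f] = (coords[f] - cen) @ rot.as_matrix().T + ref.mean(axis=0)
    return TrajectoryEnsemble(
        coords, traj.frame_interval_ps, superposed=True, source=traj.source
    )


def save_trajectory(
    traj: TrajectoryEnsemble,
    topology: str | FilePath,
    path: str | FilePath,
) -> FilePath:
    """Write the coordinates (e.g. after superposition) to a standard MD
    trajectory format chosen by the file extension (DCD/XTC/...)."""
    import mdtraj as md

    top = md.load_topology(str(topology))
    if top.n_atoms != traj.n_atoms:
        raise ValueError(
            f"atom count mismatch: topology has {top.n_atoms}, "
            f"trajectory {traj.n_atoms}"
        )
    md.Trajectory(traj.coords / 10.0, top).save(str(path))
    return FilePath(path)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD (Å) between two matched coordinate sets after optimal
    least-squares superposition (proper rotation)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have matching shapes")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(ac, bc)
    diff = bc @ rot.as_matrix().T - ac
    return float(np.sqrt((diff**2).sum() / len(a)))


@dataclass
class DistanceSeries:
    node_a: int
    node_b: int
    distances: np.ndarray  # per frame, Å
    mean: float
    std: float
    histogram: tuple[np.ndarray, np.ndarray]  # counts, bin edges

    def to_tsv(self, path: str | FilePath, frame_interval_ps: float = 1.0) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "frame": np.arange(len(self.distances)),
                "time_ps": np.arange(len(self.distances)) * frame_interval_ps,
                "distance_A": self.distances,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def pair_distance_series(
    traj: TrajectoryEnsemble,
    node_model: NodeModel,
    node_a: int,
    node_b: int,
    bins: int = 50,
) -> DistanceSeries:
    """Per-frame distance between the representative atoms of two nodes
    (e.g. a Cα–Cα distance distribution between two residues)."""
    if node_a == node_b:
        raise ValueError("node_a and node_b must differ")
    ra = node_model[node_a].representative_atom
    rb = node_model[node_b].representative_atom
    d = np.linalg.norm(traj.coords[:, ra] - traj.coords[:, rb], axis=-1)
    counts, edges = np.histogram(d, bins=bins)
    return DistanceSeries(
        node_a, node_b, d, float(d.mean()), float(d.std()), (counts, edges)
    )
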