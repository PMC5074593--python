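"""Synthetic correlated-motion trajectories with planted ground truth.

Real allosteric-network studies start from hundreds of nanoseconds of
all-atom MD.  For testing and benchmarking, this module generates
coarse-grained pseudo-trajectories whose per-node displacements follow a
*known* correlation structure: block-correlated domains (planted
communities), a chain of highly correlated nodes (the planted optimal
communication pathway between two anchors) and a weak correlated
background.  Every downstream stage — DCCM, contact network, shortest
paths, community detection — can then be checked against closed-form
ground truth.

Displacements are isotropic Gaussians with the same cross-node correlation
applied independently per Cartesian axis, so the sampled dynamic
cross-correlation matrix converges analytically to the specified
correlation matrix.

Covariance construction
-----------------------
The naive target — every consecutive planted-path edge at ``rho_path``
while the same nodes are also ``rho_block``-correlated with their whole
block — is not positive semi-definite once the path has more than one
edge (the 3×3 minor [[1, .9, .6], [.9, 1, .9], [.6, .9, 1]] has a negative
determinant).  The generator therefore builds the covariance from factor
loadings plus diagonal noise, which is PSD by construction:

* a global factor carrying the background correlation ``rho_bg``;
* one factor per block carrying ``rho_block - rho_bg`` for non-path nodes
  and a reduced mass ``m`` for path nodes;
* an AR(1)-style chain factor over the planted path with lag-one
  coefficient ``alpha`` chosen so that consecutive *in-block* path edges
  come out at exactly ``rho_path``.

Consequences (all exact, exposed by :func:`ground_truth`): a planted edge
that crosses a block boundary has correlation ``rho_path - m``; a
path/non-path pair of the same block has ``rho_bg + sqrt(m*(rho_block -
rho_bg))``.  With the default ``m = (rho_path - rho_block)/2`` every
planted edge still exceeds every background contact, so the planted path
is the unique minimum-weight route on the expected-weight graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Sequence

import numpy as np

from .model import ROLE_CA, Node, NodeModel, TrajectoryEnsemble

#: geometric parameters (Å)
CONTACT_CUTOFF = 4.5
NONCONTACT_MIN = 6.0
ATTACH_GAP = 4.0
DEFAULT_SPACING = 3.8
#: compact helical layout: bond 3.8 Å, twist 130°, rise 1.3 Å per node.
#: Gives intra-chain distances 3.99 Å (offset 2) and 4.03 Å (offset 3),
#: and > 6.4 Å for offsets >= 4 — i.e. non-adjacent intra-chain contacts
#: that survive the neighbour-exclusion rule of the network stage.
HELIX_TWIST_DEG = 130.0
HELIX_RISE = 1.3


class GeometryError(ValueError):
    """Raised when a requested layout cannot satisfy the contact contract."""


@dataclass(frozen=True)
class ChainSpec:
    chain_id: str
    n_nodes: int
    layout: str = "linear"  # "linear" | "helix"
    spacing: float = DEFAULT_SPACING

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError(f"chain {self.chain_id!r} must have >= 1 node")
        if self.layout not in ("linear", "helix"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclass(frozen=True)
class ContactSpec:
    """Declared inter-chain contact between node ``index_a`` of ``chain_a``
    and node ``index_b`` of ``chain_b`` (0-based indices within the chain)."""

    chain_a: str
    index_a: int
    chain_b: str
    index_b: int


@dataclass(frozen=True)
class GeometrySpec:
    chains: tuple[ChainSpec, ...]
    contacts: tuple[ContactSpec, ...] = ()

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("geometry spec lists no chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chain ids")


@dataclass
class Geometry:
    """Node model + mean coordinates + the pairs expected to be contacts."""

    node_model: NodeModel
    coords: np.ndarray  # (n_nodes, 3), Å
    contact_pairs: set[tuple[int, int]]  # expected non-neighbour contacts
    chain_nodes: dict[str, list[int]]


def _helix_local(n: int, spacing: float) -> np.ndarray:
    """Helix points in a local frame, node 0 at the origin, axis = +x."""
    theta = np.deg2rad(HELIX_TWIST_DEG)
    rise = HELIX_RISE * spacing / DEFAULT_SPACING
    r2 = (spacing**2 - rise**2) / (4 * np.sin(theta / 2) ** 2)
    if r2 <= 0:
        raise GeometryError(f"helix spacing {spacing} too small for rise {rise}")
    r = np.sqrt(r2)
    k = np.arange(n)
    pts = np.column_stack(
        [k * rise, r * (np.cos(k * theta) - 1.0), r * np.sin(k * theta)]
    )
    return pts


def _linear_local(n: int, spacing: float) -> np.ndarray:
    pts = np.zeros((n, 3))
    pts[:, 0] = np.arange(n) * spacing
    return pts


def make_geometry(spec: GeometrySpec) -> Geometry:
    """Place chains in space so declared contacts hold and nothing else does.

    Placement contract: every declared contact pair ends up < 4.5 Å apart;
    every pair that is neither declared, implied by a compact helical
    layout (sequence offsets 2 and 3) nor sequence-adjacent ends up > 6 Å
    apart.  Declared inter-chain contacts must join *terminal* nodes of
    both chains: an interior node flanked by two 3.8 Å neighbours cannot
    keep both of them > 6 Å away from a contact partner only 4 Å away, so
    interior attachments are rejected with a diagnostic.
    """
    by_id = {c.chain_id: c for c in spec.chains}
    for ct in spec.contacts:
        for cid, idx in ((ct.chain_a, ct.index_a), (ct.chain_b, ct.index_b)):
            if cid not in by_id:
                raise GeometryError(f"contact references unknown chain {cid!r}")
            n = by_id[cid].n_nodes
            if not 0 <= idx < n:
                raise GeometryError(f"contact index {idx} out of range for chain {cid}")
            if idx not in (0, n - 1) and n > 1:
                raise GeometryError(
                    f"declared contact must join terminal nodes; node {idx} of "
                    f"chain {cid} is interior (cannot keep its neighbours > "
                    f"{NONCONTACT_MIN} Å from the contact partner)"
                )

    placed: dict[str, np.ndarray] = {}  # chain_id -> (n,3) global coords
    axes: dict[str, np.ndarray] = {}  # chain axis (unit, +x of local frame)
    free_slot = 0

    def place(chain: ChainSpec, origin: np.ndarray, axis: np.ndarray, reverse: bool):
        local = (_helix_local if chain.layout == "helix" else _linear_local)(
            chain.n_nodes, chain.spacing
        )
        if reverse:
            # contact node (the chain's last) at the origin, body extending +x
            local = local[-1] - local
        # orthonormal frame with x = axis
        x = axis / np.linalg.norm(axis)
        ref = np.array([0.0, 0.0, 1.0]) if abs(x[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        y = np.cross(ref, x)
        y /= np.linalg.norm(y)
        z = np.cross(x, y)
        frame = np.column_stack([x, y, z])
        placed[chain.chain_id] = origin + local @ frame.T
        axes[chain.chain_id] = x

    for chain in spec.chains:
        anchor = None
        for ct in spec.contacts:
            if ct.chain_a == chain.chain_id and ct.chain_b in placed:
                anchor = (ct.chain_b, ct.index_b, ct.index_a)
            elif ct.chain_b == chain.chain_id and ct.chain_a in placed:
                anchor = (ct.chain_a, ct.index_a, ct.index_b)
            if anchor:
                break
        if anchor is None:
            origin = np.array([0.0, 30.0 * free_slot, 0.0])
            free_slot += 1
            place(chain, origin, np.array([1.0, 0.0, 0.0]), reverse=False)
        else:
            partner_id, partner_idx, own_idx = anchor
            pcoords = placed[partner_id]
            p_n = by_id[partner_id].n_nodes
            if partner_idx not in (0, p_n - 1):
                raise GeometryError(
                    f"contact node {partner_idx} of chain {partner_id} is interior"
                )
            # outward direction at the partner terminus
            paxis = axes[partner_id]
            outward = paxis if partner_idx == p_n - 1 else -paxis
            if p_n == 1:
                outward = paxis
            origin = pcoords[partner_idx] + ATTACH_GAP * outward
            place(chain, origin, outward, reverse=(own_idx == chain.n_nodes - 1))

    # assemble node model
    nodes: list[Node] = []
    coords_list: list[np.ndarray] = []
    chain_nodes: dict[str, list[int]] = {}
    nid = 0
    for chain in spec.chains:
        chain_nodes[chain.chain_id] = []
        for k in range(chain.n_nodes):
            nodes.append(
                Node(
                    node_id=nid,
                    chain_id=chain.chain_id,
                    resnum=k + 1,
                    resname="ALA",
                    role=ROLE_CA,
                    member_atoms=(nid,),
                    representative_atom=nid,
                )
            )
            chain_nodes[chain.chain_id].append(nid)
            coords_list.append(placed[chain.chain_id][k])
            nid += 1
    coords = np.array(coords_list)
    node_model = NodeModel(nodes, n_atoms=nid)

    # expected contacts: declared inter-chain + helix-implied intra-chain
    expected: set[tuple[int, int]] = set()
    for ct in spec.contacts:
        u = chain_nodes[ct.chain_a][ct.index_a]
        v = chain_nodes[ct.chain_b][ct.index_b]
        expected.add((min(u, v), max(u, v)))
    for chain in spec.chains:
        if chain.layout == "helix":
            ids = chain_nodes[chain.chain_id]
            for off in (2, 3):
                for a, b in zip(ids, ids[off:]):
                    expected.add((a, b))

    _validate_geometry(node_model, coords, expected)
    return Geometry(node_model, coords, expected, chain_nodes)


def _validate_geometry(
    node_model: NodeModel, coords: np.ndarray, expected: set[tuple[int, int]]
) -> None:
    n = len(node_model)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    neighbors = node_model.neighbor_pairs()
    bad: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            pair = (i, j)
            if pair in expected:
                if d[i, j] >= CONTACT_CUTOFF:
                    bad.append(f"declared contact {i}-{j} at {d[i, j]:.2f} Å >= 4.5 Å")
            elif pair not in neighbors and d[i, j] <= NONCONTACT_MIN:
                bad.append(
                    f"undeclared pair {i}-{j} at {d[i, j]:.2f} Å <= {NONCONTACT_MIN} Å"
                )
    if bad:
        raise GeometryError("geometry violates contact contract: " + "; ".join(bad))


# ---------------------------------------------------------------------------
# covariance


def make_covariance(
    n_nodes: int,
    blocks: Sequence[int] | dict[str, Sequence[int]],
    planted_path: Sequence[int] = (),
    rho_path: float = 0.9,
    rho_block: float = 0.6,
    rho_bg: float = 0.1,
    path_block_mass: float | None = None,
) -> np.ndarray:
    """Unit-diagonal PSD correlation matrix with planted structure.

    ``blocks`` is either a per-node label sequence or a mapping
    ``{label: node ids}``.  Requires ``0 <= rho_bg < rho_block < rho_path
    <= 1``.  See the module docstring for the factor construction and the
    exact off-nominal values it produces.
    """
    if not 0 <= rho_bg < rho_block < rho_path <= 1:
        raise ValueError(
            f"need 0 <= rho_bg < rho_block < rho_path <= 1, got "
            f"({rho_bg}, {rho_block}, {rho_path})"
        )
    labels = _block_labels(n_nodes, blocks)
    path = list(planted_path)
    if len(set(path)) != len(path):
        raise ValueError("planted path revisits a node")
    for p in path:
        if not 0 <= p < n_nodes:
            raise ValueError(f"planted path node {p} out of range")

    m = path_block_mass
    if m is None:
        m = 0.5 * (rho_path - rho_block)
    if not 0 <= m <= rho_path - rho_bg:
        raise ValueError(f"path_block_mass {m} out of range")

    C = np.full((n_nodes, n_nodes), rho_bg)
    on_path = np.zeros(n_nodes, dtype=bool)
    on_path[path] = True
    load = np.where(on_path, np.sqrt(m), np.sqrt(rho_block - rho_bg))
    same_block = labels[:, None] == labels[None, :]
    C += np.outer(load, load) * same_block

    if len(path) >= 2:
        chain_var = 1.0 - rho_bg - m
        denom = chain_var if chain_var > 0 else 1.0
        alpha = (rho_path - rho_bg - m) / denom
        pos = np.arange(len(path))
        ar = chain_var * alpha ** np.abs(pos[:, None] - pos[None, :])
        C[np.ix_(path, path)] += ar - np.diag(np.diag(ar))  # diag handled below

    np.fill_diagonal(C, 1.0)
    # PSD by construction; assert, do not repair
    eigmin = float(np.linalg.eigvalsh(C)[0])
    assert eigmin >= -1e-10, f"covariance construction not PSD (eigmin={eigmin})"
    return C


def _block_labels(
    n_nodes: int, blocks: Sequence[int] | dict[str, Sequence[int]]
) -> np.ndarray:
    if isinstance(blocks, dict):
        labels = np.full(n_nodes, -1, dtype=int)
        for k, (name, ids) in enumerate(sorted(blocks.items())):
            for i in ids:
                labels[i] = k
        if np.any(labels < 0):
            raise ValueError("block mapping does not cover all nodes")
        return labels
    labels = np.asarray(list(blocks), dtype=int)
    if labels.shape != (n_nodes,):
        raise ValueError("block labels must cover every node")
    return labels


# ---------------------------------------------------------------------------
# the assembled model


@dataclass
class SyntheticModel:
    node_model: NodeModel
    mean_coords: np.ndarray  # (n, 3) Å
    covariance: np.ndarray  # (n, n) unit-diagonal correlation
    planted_path: tuple[int, ...]
    planted_partition: np.ndarray  # per-node block label
    contact_pairs: set[tuple[int, int]]
    frame_interval_ps: float = 1.0
    amplitude: float = 0.3  # per-axis displacement scale, Å
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        C = self.covariance
        if not np.allclose(C, C.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.abs(C) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("covariance must have unit diagonal")
        d = np.linalg.norm(
            self.mean_coords[list(self.planted_path[:-1])]
            - self.mean_coords[list(self.planted_path[1:])],
            axis=-1,
        ) if len(self.planted_path) > 1 else np.array([])
        if d.size and np.any(d >= CONTACT_CUTOFF):
            raise ValueError("consecutive planted-path nodes must be < 4.5 Å apart")


@dataclass(frozen=True)
class GroundTruth:
    planted_path: tuple[int, ...]
    planted_partition: tuple[int, ...]
    expected_edge_corr: dict[tuple[int, int], float]  # planted edges, exact
    expected_edge_weights: dict[tuple[int, int], float]  # -ln of the above
    nominal_edge_weight: float  # -ln(rho_path)
    background_contact_corr: dict[tuple[int, int], float]
    margin: float  # min planted edge corr - max background contact corr


def ground_truth(model: SyntheticModel) -> GroundTruth:
    """Expose what downstream recovery tests assert against.

    Expected edge weights are −ln(ρ) of the *exact* constructed
    correlations; for in-block planted edges these equal −ln(rho_path).
    """
    C = model.covariance
    path = model.planted_path
    edges = list(zip(path, path[1:]))
    corr = {(min(u, v), max(u, v)): float(C[u, v]) for u, v in edges}
    weights = {e: -float(np.log(abs(c))) if c != 0 else np.inf for e, c in corr.items()}
    background = {
        e: float(C[e]) for e in model.contact_pairs if e not in corr
    }
    margin = (
        min(corr.values()) - max(background.values()) if corr and background else np.nan
    )
    rho_path = model.params.get("rho_path")
    nominal = -float(np.log(rho_path)) if rho_path else min(weights.values())
    return GroundTruth(
        planted_path=path,
        planted_partition=tuple(int(x) for x in model.planted_partition),
        expected_edge_corr=corr,
        expected_edge_weights=weights,
        nominal_edge_weight=nominal,
        background_contact_corr=background,
        margin=float(margin),
    )


def sample_trajectory(
    model: SyntheticModel, n_frames: int, seed: int, amplitude: float | None = None
) -> TrajectoryEnsemble:
    """Draw frames = mean + correlated Gaussian displacements.

    The node-displacement correlation ``C`` is applied independently per
    Cartesian axis with per-node amplitude ``model.amplitude`` (Å), so the
    sample DCCM converges to ``C`` exactly.  A seed is mandatory: all
    stochastic content of the pipeline must be reproducible.
    """
    if n_frames < 2:
        raise ValueError("need n_frames >= 2 (correlations undefined otherwise)")
    if seed is None:
        raise ValueError("sample_trajectory requires an explicit seed")
    amp = model.amplitude if amplitude is None else amplitude
    n = len(model.node_model)
    L = _psd_factor(model.covariance)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((3, n_frames, n))
    disp = z @ L.T  # (3, frames, n)
    coords = model.mean_coords[None, :, :] + amp * np.moveaxis(disp, 0, -1)
    return TrajectoryEnsemble(
        coords,
        frame_interval_ps=model.frame_interval_ps,
        superposed=True,  # no rigid-body component by construction
        source=f"synthetic(seed={seed}, n_frames={n_frames})",
    )


def _psd_factor(C: np.ndarray) -> np.ndarray:
    """Cholesky if possible, symmetric eigen-factor for singular matrices."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(C)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


# ---------------------------------------------------------------------------
# canonical planted benchmark


def _skip_path(ids: Sequence[int]) -> list[int]:
    """Route from first to last of a compact chain using sequence steps of
    3 or 2 — exactly the offsets that are contacts but not excluded
    neighbours in the helical layout."""
    n = len(ids)
    if n < 3:
        raise ValueError("need >= 3 nodes per block for a planted path")
    path = [0]
    pos = 0
    while n - 1 - pos > 4:
        pos += 3
        path.append(pos)
    rem = n - 1 - pos
    if rem == 4:
        path += [pos + 2, pos + 4]
    elif rem > 0:
        path.append(pos + rem)
    return [ids[p] for p in path]


def make_planted_model(
    n_per_block: int = 10,
    rho_path: float = 0.9,
    rho_block: float = 0.6,
    rho_bg: float = 0.1,
    path_block_mass: float | None = None,
    amplitude: float = 0.3,
    frame_interval_ps: float = 1.0,
) -> SyntheticModel:
    """Two helical blocks joined end-to-end by a single bridging contact.

    The planted path runs through block A in sequence steps of 3 (contacts
    that survive neighbour exclusion), crosses the bridge, and continues
    through block B.  The bridge is the only inter-block contact, so the
    planted partition is the two chains.
    """
    spec = GeometrySpec(
        chains=(
            ChainSpec("A", n_per_block, layout="helix"),
            ChainSpec("B", n_per_block, layout="helix"),
        ),
        contacts=(ContactSpec("A", n_per_block - 1, "B", 0),),
    )
    geo = make_geometry(spec)
    path = _skip_path(geo.chain_nodes["A"]) + _skip_path(geo.chain_nodes["B"])
    labels = np.array(
        [0] * n_per_block + [1] * n_per_block, dtype=int
    )
    C = make_covariance(
        len(geo.node_model),
        labels,
        planted_path=path,
        rho_path=rho_path,
        rho_block=rho_block,
        rho_bg=rho_bg,
        path_block_mass=path_block_mass,
    )
    m = (
        0.5 * (rho_path - rho_block)
        if path_block_mass is None
        else path_block_mass
    )
    return SyntheticModel(
        node_model=geo.node_model,
        mean_coords=geo.coords,
        covariance=C,
        planted_path=tuple(path),
        planted_partition=labels,
        contact_pairs=geo.contact_pairs,
        frame_interval_ps=frame_interval_ps,
        amplitude=amplitude,
        params=dict(
            rho_path=rho_path,
            rho_block=rho_block,
            rho_bg=rho_bg,
            path_block_mass=m,
            n_per_block=n_per_block,
        ),
    )


# ---------------------------------------------------------------------------
# on-disk round trip


def write_system(
    model: SyntheticModel,
    traj: TrajectoryEnsemble,
    outdir: str | FilePath,
    seed: int | None = None,
) -> dict[str, FilePath]:
    """Write topology (PDB), coordinates (DCD) and a JSON ground-truth sidecar."""
    import mdtraj as md

    outdir = FilePath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    top = md.Topology()
    carbon = md.element.carbon
    for cid in dict.fromkeys(n.chain_id for n in model.node_model):
        ch = top.add_chain()
        for node in model.node_model:
            if node.chain_id != cid:
                continue
            res = top.add_residue(node.resname, ch, resSeq=node.resnum)
            top.add_atom("CA", carbon, res)
    pdb_path = outdir / "nodes.pdb"
    dcd_path = outdir / "traj.dcd"
    md.Trajectory(model.mean_coords[None] / 10.0, top).save_pdb(str(pdb_path))
    md.Trajectory(traj.coords / 10.0, top).save_dcd(str(dcd_path))
    gt = ground_truth(model)
    sidecar = {
        "planted_path": list(gt.planted_path),
        "planted_partition": list(gt.planted_partition),
        "covariance_params": model.params,
        "frame_interval_ps": model.frame_interval_ps,
        "amplitude": model.amplitude,
        "seed": seed,
    }
    json_path = outdir / "ground_truth.json"
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"topology": pdb_path, "trajectory": dcd_path, "ground_truth": json_path}
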