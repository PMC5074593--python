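"""Topology parsing, node-model construction, superposition, distances."""

import numpy as np
import pytest

import dynapath as dp
from dynapath.model import (
    ROLE_BASE,
    ROLE_CA,
    ROLE_PHOSPHATE,
    NodeModel,
    TrajectoryEnsemble,
)
from dynapath.synthetic import ChainSpec, GeometrySpec, make_covariance, make_geometry
from dynapath.trajio import pair_distance_series, rmsd_between, superpose

from conftest import point_node_model


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z, element):
    name_field = name if len(name) == 4 else f" {name:<3}"
    return (
        f"ATOM  {serial:>5} {name_field} {resname:<3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
    )


def write_protein_pdb(path, n_res=10, skip_ca_at=None):
    lines = []
    serial = 1
    for r in range(1, n_res + 1):
        x = 3.8 * r
        atoms = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
        for name, elem in atoms:
            if name == "CA" and r == skip_ca_at:
                continue
            lines.append(_pdb_atom(serial, name, "GLY", "A", r, x, 0.0, 0.0, elem))
            serial += 1
            x += 0.4
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


_DNA_BASE = {
    "DA": ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"],
    "DG": ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"],
    "DC": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "DT": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"],
}
_SUGAR_PHOS = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"]


def write_dna_pdb(path, sequence=("DA", "DT", "DG", "DC")):
    lines = []
    serial = 1
    for r, resname in enumerate(sequence, start=1):
        x0 = 7.0 * r
        for k, name in enumerate(_SUGAR_PHOS + _DNA_BASE[resname]):
            elem = name[0] if name[0] in "PONC" else "C"
            lines.append(
                _pdb_atom(serial, name, resname, "D", r, x0 + 0.3 * k, 0.0, 0.0, elem)
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadTopology:
    def test_protein_only(self, tmp_path):
        pdb = write_protein_pdb(tmp_path / "prot.pdb")
        nm = dp.load_topology(pdb)
        assert len(nm) == 10
        assert all(n.role == ROLE_CA for n in nm)
        assert [n.resnum for n in nm] == list(range(1, 11))

    def test_dna_strand_two_nodes_per_nucleotide(self, tmp_path):
        pdb = write_dna_pdb(tmp_path / "dna.pdb")
        nm = dp.load_topology(pdb)
        assert len(nm) == 8
        roles = [n.role for n in nm]
        assert roles.count(ROLE_BASE) == 4
        assert roles.count(ROLE_PHOSPHATE) == 4
        # purines anchored at N9, pyrimidines at N1; every atom assigned to
        # exactly one of the two nodes
        import mdtraj as md

        top = md.load_topology(str(pdb))
        names = {a.index: a.name for a in top.atoms}
        for node in nm:
            if node.role == ROLE_BASE:
                expected = "N9" if node.resname in ("DA", "DG") else "N1"
                assert names[node.representative_atom] == expected
            elif node.role == ROLE_PHOSPHATE:
                assert names[node.representative_atom] == "P"
        base = next(n for n in nm if n.role == ROLE_BASE)
        phos = next(
            n
            for n in nm
            if n.role == ROLE_PHOSPHATE and n.resnum == base.resnum
        )
        assert not set(base.member_atoms) & set(phos.member_atoms)

    def test_missing_ca_is_an_error_naming_the_residue(self, tmp_path):
        pdb = write_protein_pdb(tmp_path / "bad.pdb", skip_ca_at=4)
        with pytest.raises(ValueError, match="GLY4"):
            dp.load_topology(pdb)

    def test_node_count_identity(self, tmp_path):
        """#nodes == #amino acids + 2 × #nucleotides."""
        nm_p = dp.load_topology(write_protein_pdb(tmp_path / "p.pdb", n_res=7))
        nm_d = dp.load_topology(write_dna_pdb(tmp_path / "d.pdb"))
        assert len(nm_p) == 7
        assert len(nm_d) == 2 * 4


class TestLoadTrajectory:
    def test_concatenation_preserves_order(self, tmp_path, planted_model):
        t1 = dp.sample_trajectory(planted_model, 30, seed=1)
        t2 = dp.sample_trajectory(planted_model, 20, seed=2)
        d1 = dp.write_system(planted_model, t1, tmp_path / "a", seed=1)
        d2 = dp.write_system(planted_model, t2, tmp_path / "b", seed=2)
        nm = dp.load_topology(d1["topology"])
        traj = dp.load_trajectory(
            [d1["trajectory"], d2["trajectory"]], nm, topology=d1["topology"]
        )
        assert traj.n_frames == 50
        assert np.allclose(traj.coords[:30], t1.coords, atol=1e-3)
        assert np.allclose(traj.coords[30:], t2.coords, atol=1e-3)

    def test_atom_count_mismatch_rejected(self, tmp_path, planted_model):
        t1 = dp.sample_trajectory(planted_model, 5, seed=1)
        d1 = dp.write_system(planted_model, t1, tmp_path / "a", seed=1)
        wrong = point_node_model(7)
        with pytest.raises(ValueError, match="mismatch"):
            dp.load_trajectory([d1["trajectory"]], wrong, topology=d1["topology"])

    def test_save_superposed_round_trip(self, tmp_path, planted_model):
        from dynapath.trajio import save_trajectory

        t1 = dp.sample_trajectory(planted_model, 10, seed=4)
        d1 = dp.write_system(planted_model, t1, tmp_path / "a", seed=4)
        nm = dp.load_topology(d1["topology"])
        fitted = superpose(
            dp.load_trajectory([d1["trajectory"]], nm, topology=d1["topology"]),
            nm.representative_atoms,
        )
        out = save_trajectory(fitted, d1["topology"], tmp_path / "fit.dcd")
        back = dp.load_trajectory([out], nm, topology=d1["topology"])
        assert np.allclose(back.coords, fitted.coords, atol=1e-3)


class TestSuperpose:
    def _random_rigid_frames(self, seed, n_atoms=12, n_frames=15):
        rng = np.random.default_rng(seed)
        base = rng.uniform(-5, 5, size=(n_atoms, 3))
        from scipy.spatial.transform import Rotation

        frames = []
        for _ in range(n_frames):
            rot = Rotation.random(random_state=rng).as_matrix()
            shift = rng.uniform(-10, 10, size=3)
            frames.append(base @ rot.T + shift)
        return base, np.array(frames)

    def test_rigid_motion_removed(self):
        _, frames = self._random_rigid_frames(0)
        traj = TrajectoryEnsemble(frames)
        fitted = superpose(traj)
        assert fitted.superposed
        spread = fitted.coords.std(axis=0).max()
        assert spread < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(size=(10, 8, 3))
        once = superpose(TrajectoryEnsemble(frames))
        twice = superpose(once)
        assert np.allclose(once.coords, twice.coords, atol=1e-6)

    def test_rmsd_to_mean_non_increasing(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(scale=3.0, size=(25, 10, 3))

        def mean_rmsd(c):
            mu = c.mean(axis=0)
            return np.sqrt(((c - mu) ** 2).sum(axis=(1, 2)) / c.shape[1]).mean()

        t0 = TrajectoryEnsemble(frames)
        t1 = superpose(t0)
        t2 = superpose(t1)
        assert mean_rmsd(t1.coords) <= mean_rmsd(t0.coords) + 1e-6
        assert mean_rmsd(t2.coords) <= mean_rmsd(t1.coords) + 1e-6

    def test_frame_order_invariance(self):
        _, frames = self._random_rigid_frames(3)
        rng = np.random.default_rng(4)
        perm = rng.permutation(frames.shape[0])
        a = superpose(TrajectoryEnsemble(frames)).coords
        b = superpose(TrajectoryEnsemble(frames[perm])).coords
        assert np.allclose(a[perm], b, atol=1e-6)

    def test_too_few_selection_atoms(self):
        traj = TrajectoryEnsemble(np.zeros((5, 4, 3)))
        with pytest.raises(ValueError):
            superpose(traj, selection=[0, 1])

    def test_rmsd_between_identical_is_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(20, 3))
        from scipy.spatial.transform import Rotation

        b = a @ Rotation.random(random_state=rng).as_matrix().T + 4.2
        assert rmsd_between(a, b) < 1e-9


class TestPairDistances:
    def test_static_pair(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = 5.0
        nm = point_node_model(2)
        ds = pair_distance_series(TrajectoryEnsemble(coords), nm, 0, 1)
        assert np.allclose(ds.distances, 5.0)
        assert ds.std == pytest.approx(0.0)

    def test_identical_nodes_rejected(self):
        nm = point_node_model(2)
        with pytest.raises(ValueError):
            pair_distance_series(
                TrajectoryEnsemble(np.zeros((4, 2, 3))), nm, 1, 1
            )

    def test_mean_distance_matches_noncentral_chi_expectation(self):
        """Monte-Carlo vs analytic moments: for two independent isotropic
        Gaussian nodes, d²/(2a²) follows a noncentral chi-square (k=3,
        λ=μ²/2a²); the empirical mean distance must agree within 3 SEM."""
        from scipy.stats import ncx2

        mu, amp, n = 8.0, 0.5, 20000
        C = make_covariance(2, [0, 1], rho_block=0.5, rho_bg=0.0)
        assert C[0, 1] == 0.0
        geo = make_geometry(GeometrySpec(chains=(ChainSpec("A", 2, spacing=mu),)))
        model = dp.SyntheticModel(
            node_model=geo.node_model,
            mean_coords=geo.coords,
            covariance=C,
            planted_path=(),
            planted_partition=np.array([0, 1]),
            contact_pairs=set(),
            amplitude=amp,
        )
        traj = dp.sample_trajectory(model, n, seed=9)
        ds = pair_distance_series(traj, model.node_model, 0, 1)
        s2 = 2 * amp**2
        expected = np.sqrt(s2) * ncx2.expect(
            np.sqrt, args=(3, mu**2 / s2)
        )
        assert abs(ds.mean - expected) < 3 * ds.std / np.sqrt(n)
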