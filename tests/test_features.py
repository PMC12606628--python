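import numpy as np
import pytest

from qdpr.features import (
    FeatureEntry,
    FeatureSchema,
    by_residue_schema,
    compute_ks_hbond,
    compute_rmsf,
    compute_sasa,
    compute_wn_hbond,
    discard_equilibration,
    extract_features,
    fit_pca_basis,
    gb1_schema,
    golden_spiral_points,
    kabsch_sander_energy,
    project_weights,
)
from qdpr.synthetic import simulate_trajectory
from qdpr.trajectory import Topology, TrajectoryEnsemble

from tests.conftest import single_atom_trajectory


def _rigid_transform(coords, rng):
    """Random proper rotation + translation applied to every frame."""
    q = rng.normal(size=(3, 3))
    r, _ = np.linalg.qr(q)
    if np.linalg.det(r) < 0:
        r[:, 0] *= -1
    t = rng.normal(scale=10.0, size=3)
    return coords @ r.T + t


class TestEquilibrationDiscard:
    def test_ten_percent_of_ten_frames(self):
        t = single_atom_trajectory(n_frames=10)
        assert discard_equilibration(t, 0.1).n_frames == 9

    def test_hundred_ns_every_ten_ps(self):
        # 100 ns sampled every 10 ps -> 10,000 frames; 10% discard -> 9,000
        t = single_atom_trajectory(n_frames=10_000)
        assert discard_equilibration(t, 0.1).n_frames == 9_000

    def test_zero_fraction_is_identity(self):
        t = single_atom_trajectory(n_frames=7)
        out = discard_equilibration(t, 0.0)
        assert np.array_equal(out.coordinates, t.coordinates)

    def test_per_segment_discard(self):
        top = Topology(("X",), ("C",), np.array([1.6]), np.array([1]))
        t = TrajectoryEnsemble(
            np.zeros((30, 1, 3)), top, segments=((0, 10), (10, 30))
        )
        out = discard_equilibration(t, 0.1)
        assert out.segments == ((0, 9), (9, 27))

    @pytest.mark.parametrize("fraction", [-0.1, 1.0, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        t = single_atom_trajectory(n_frames=5)
        with pytest.raises(ValueError):
            discard_equilibration(t, fraction)


class TestRMSF:
    def _traj(self, coords, n_res):
        names = tuple("CA" for _ in range(n_res))
        top = Topology(names, tuple("C" * n_res), np.full(n_res, 1.7),
                       np.arange(1, n_res + 1))
        return TrajectoryEnsemble(coords, top)

    def test_static_trajectory_is_zero(self):
        base = np.random.default_rng(0).normal(size=(5, 3)) * 5
        coords = np.repeat(base[None], 4, axis=0)
        assert np.allclose(compute_rmsf(self._traj(coords, 5)), 0.0, atol=1e-10)

    def test_single_oscillating_atom(self):
        """One atom alternating +/- d along x -> RMSF ~= d for that residue.

        The least-squares fit absorbs the centroid shift d/n, so with many
        anchor atoms the moving residue carries essentially all the motion.
        """
        d = 0.25
        n = 40
        base = np.random.default_rng(0).normal(size=(n, 3)) * 10
        frames = np.repeat(base[None], 2, axis=0)
        frames[0, 2, 0] += d
        frames[1, 2, 0] -= d
        r = compute_rmsf(self._traj(frames, n))
        assert r[2] == pytest.approx(d, rel=0.08)
        assert r[2] > 10 * np.delete(r, 2).max()

    def test_isotropic_jitter_matches_sigma_sqrt3(self):
        """Gaussian jitter of per-axis std sigma -> RMSF = sigma*sqrt(3),
        after correcting for the 6 rigid-body degrees of freedom the
        superposition removes from the 3n total."""
        rng = np.random.default_rng(1)
        sigma = 0.2
        n = 100
        base = rng.normal(size=(n, 3)) * 10
        coords = base[None] + rng.normal(scale=sigma, size=(10_000, n, 3))
        r = compute_rmsf(self._traj(coords, n))
        expected = sigma * np.sqrt(3) * np.sqrt(1 - 6 / (3 * n))
        assert np.allclose(r, expected, rtol=0.03)

    def test_rigid_body_invariance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 3)) * 6
        coords = base[None] + rng.normal(scale=0.3, size=(50, 6, 3))
        r1 = compute_rmsf(self._traj(coords, 6))
        moved = np.stack([_rigid_transform(f, rng) for f in coords])
        r2 = compute_rmsf(self._traj(moved, 6))
        assert np.allclose(r1, r2, rtol=1e-6)

    def test_missing_alpha_carbon(self):
        top = Topology(("N",), ("N",), np.array([1.55]), np.array([1]))
        t = TrajectoryEnsemble(np.zeros((3, 1, 3)), top)
        with pytest.raises(ValueError, match="residue 1"):
            compute_rmsf(t)


class TestKabschSander:
    def test_formula_hand_value(self):
        # 0.084 * 332 * (1/2 + 1/3 - 1/1.5 - 1/3.5) = -3.32 kcal/mol
        assert kabsch_sander_energy(2.0, 3.0, 1.5, 3.5) == pytest.approx(-3.32)

    def test_far_apart_residues_contribute_nothing(self):
        bb = []
        for shift in (0.0, 100.0):
            bb += [[shift, 0, 0], [shift + 1.5, 0, 0], [shift + 2.5, 1, 0],
                   [shift + 2.5, 2.2, 0]]
        top = Topology(("N", "CA", "C", "O") * 2, ("N", "C", "C", "O") * 2,
                       np.array([1.55, 1.7, 1.7, 1.52] * 2),
                       np.array([1, 1, 1, 1, 2, 2, 2, 2]))
        t = TrajectoryEnsemble(np.asarray(bb, float)[None], top)
        assert np.allclose(compute_ks_hbond(t), 0.0)

    def test_ideal_helix_i_to_i_plus_4(self, helix_trajectory):
        from qdpr.features import KS_CUTOFF, _ks_frame_energies

        e, donors, acceptors = _ks_frame_energies(
            helix_trajectory.coordinates, helix_trajectory
        )
        bonds = {
            (int(donors[i]) + 1, int(acceptors[j]) + 1)
            for i, j in np.argwhere(e[0] < KS_CUTOFF)
        }
        n = helix_trajectory.topology.n_residues
        assert bonds == {(i + 4, i) for i in range(1, n - 3)}

    def test_rigid_body_invariance(self, helix_trajectory):
        rng = np.random.default_rng(3)
        ref = compute_ks_hbond(helix_trajectory)
        moved = TrajectoryEnsemble(
            np.stack([_rigid_transform(f, rng) for f in helix_trajectory.coordinates]),
            helix_trajectory.topology,
        )
        assert np.allclose(ref, compute_ks_hbond(moved), rtol=1e-6, atol=1e-9)

    def test_mdtraj_cross_check(self, helix_trajectory):
        """Independent oracle: mdtraj's Kabsch-Sander on the same helix."""
        md = pytest.importorskip("mdtraj")
        traj = helix_trajectory.to_mdtraj()
        mats = md.kabsch_sander(traj)
        ours = compute_ks_hbond(helix_trajectory)
        theirs = np.zeros(helix_trajectory.topology.n_residues)
        m = mats[0].tocoo()
        for d_res, a_res, e in zip(m.row, m.col, m.data):
            theirs[d_res] += e
            theirs[a_res] += e
        # H placement conventions differ slightly (bisector vs carbonyl copy)
        assert np.corrcoef(ours, theirs)[0, 1] > 0.99
        assert np.allclose(ours, theirs, atol=0.6)


class TestWernetNilsson:
    def test_far_atoms_no_bonds(self):
        coords = np.array([[[0, 0, 0], [1.0, 0, 0], [50, 0, 0]]], float)
        top = Topology(("N", "H", "O"), ("N", "H", "O"),
                       np.array([1.55, 1.2, 1.52]), np.array([1, 1, 2]))
        assert np.allclose(compute_wn_hbond(TrajectoryEnsemble(coords, top)), 0)

    def test_ideal_linear_bond_counted_once_per_participant(self):
        coords = np.array([[[0, 0, 0], [1.0, 0, 0], [2.8, 0, 0]]], float)
        top = Topology(("N", "H", "O"), ("N", "H", "O"),
                       np.array([1.55, 1.2, 1.52]), np.array([1, 1, 3]))
        out = compute_wn_hbond(TrajectoryEnsemble(coords, top))
        assert out[0] == 1.0 and out[2] == 1.0

    def test_cone_criterion_boundary(self):
        # delta = 30 deg -> cutoff 3.3 - 0.00044*900 = 2.904 A
        delta = np.deg2rad(30.0)
        for r_da, expect in ((2.90, 1.0), (2.91, 0.0)):
            a_pos = np.array([r_da * np.cos(delta), r_da * np.sin(delta), 0.0])
            coords = np.array([[[0, 0, 0], [1.0, 0, 0], a_pos]], float)
            top = Topology(("N", "H", "O"), ("N", "H", "O"),
                           np.array([1.55, 1.2, 1.52]), np.array([1, 1, 3]))
            out = compute_wn_hbond(TrajectoryEnsemble(coords, top))
            assert out[0] == expect

    def test_rigid_rotation_invariance(self, helix_trajectory):
        rng = np.random.default_rng(4)
        ref = compute_wn_hbond(helix_trajectory)
        moved = TrajectoryEnsemble(
            np.stack([_rigid_transform(f, rng) for f in helix_trajectory.coordinates]),
            helix_trajectory.topology,
        )
        assert np.allclose(ref, compute_wn_hbond(moved), atol=1e-9)

    def test_no_polar_hydrogens_warns_and_zeroes(self):
        top = Topology(("N", "O"), ("N", "O"), np.array([1.55, 1.52]),
                       np.array([1, 2]))
        t = TrajectoryEnsemble(np.zeros((1, 2, 3)), top)
        with pytest.warns(UserWarning):
            assert np.allclose(compute_wn_hbond(t), 0)


class TestSASA:
    def test_isolated_sphere_analytic(self):
        t = single_atom_trajectory(radius=1.6)
        area = compute_sasa(t, probe_radius=1.4, n_sphere_points=960)[0]
        assert area == pytest.approx(4 * np.pi * 3.0**2, rel=0.01)

    def test_coincident_atoms_count_one_sphere(self):
        top = Topology(("X", "Y"), ("C", "C"), np.array([1.6, 1.6]),
                       np.array([1, 2]))
        t = TrajectoryEnsemble(np.zeros((1, 2, 3)), top)
        total = compute_sasa(t, 1.4, 960).sum()
        assert total == pytest.approx(4 * np.pi * 3.0**2, rel=0.01)

    def test_two_sphere_union_converges_with_lattice_density(self):
        r_exp, d = 3.0, 2.0
        analytic = 4 * np.pi * r_exp**2 * (1 + d / (2 * r_exp))
        top = Topology(("X", "Y"), ("C", "C"), np.array([1.6, 1.6]),
                       np.array([1, 2]))
        coords = np.array([[[0, 0, 0], [d, 0, 0]]], float)
        t = TrajectoryEnsemble(coords, top)
        errs = [abs(compute_sasa(t, 1.4, n).sum() - analytic) / analytic
                for n in (100, 500, 2000)]
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.005

    def test_mdtraj_cross_check(self, helix_trajectory):
        md = pytest.importorskip("mdtraj")
        ours = compute_sasa(helix_trajectory, 1.4, 960)
        theirs = md.shrake_rupley(
            helix_trajectory.to_mdtraj(), probe_radius=0.14, n_sphere_points=960,
            mode="residue",
        )[0] * 100.0  # nm^2 -> A^2
        # radii tables differ slightly between implementations
        assert np.corrcoef(ours, theirs)[0, 1] > 0.98
        assert np.abs(ours - theirs).max() / theirs.max() < 0.12

    def test_invalid_probe(self):
        with pytest.raises(ValueError):
            compute_sasa(single_atom_trajectory(), probe_radius=-1.0)

    def test_golden_spiral_is_unit_and_deterministic(self):
        pts = golden_spiral_points(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, golden_spiral_points(500))


class TestPCA:
    def _ca_traj(self, coords):
        n = coords.shape[1]
        top = Topology(tuple("CA" for _ in range(n)), tuple("C" * n),
                       np.full(n, 1.7), np.arange(1, n + 1))
        return TrajectoryEnsemble(coords, top)

    def test_single_axis_motion_concentrates_variance(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(6, 3)) * 8
        coords = np.repeat(base[None], 200, axis=0)
        coords[:, 2, 0] += rng.normal(scale=0.5, size=200)
        basis = fit_pca_basis(self._ca_traj(coords), n_components=4)
        frac = basis.component_variances[0] / basis.component_variances.sum()
        assert frac > 0.999

    def test_components_orthonormal(self, toy_protein, dynamics_model):
        t = simulate_trajectory(toy_protein, None, dynamics_model, 200, seed=6)
        basis = fit_pca_basis(t, n_components=10)
        gram = basis.components @ basis.components.T
        assert np.allclose(gram, np.eye(10), atol=1e-8)

    def test_weights_sum_to_one(self, toy_protein, dynamics_model):
        t = simulate_trajectory(toy_protein, None, dynamics_model, 200, seed=7)
        basis = fit_pca_basis(t, n_components=8)
        w = project_weights(t, basis)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_self_projection_matches_own_variances(self, toy_protein, dynamics_model):
        t = simulate_trajectory(toy_protein, None, dynamics_model, 300, seed=8)
        basis = fit_pca_basis(t, n_components=6)
        w = project_weights(t, basis)
        expected = basis.component_variances / basis.component_variances.sum()
        assert np.allclose(w, expected, rtol=1e-6)

    def test_constructed_single_mode_motion(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(5, 3)) * 6
        mode = rng.normal(size=(5, 3))
        mode /= np.linalg.norm(mode)
        amp = rng.normal(scale=1.0, size=300)
        coords_a = np.repeat(base[None], 300, axis=0) + amp[:, None, None] * mode
        basis = fit_pca_basis(self._ca_traj(coords_a), n_components=3)
        amp_b = rng.normal(scale=0.7, size=200)
        coords_b = np.repeat(base[None], 200, axis=0) + amp_b[:, None, None] * mode
        w = project_weights(self._ca_traj(coords_b), basis)
        assert w[0] > 0.999

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(5, 4, 3))
        with pytest.raises(ValueError):
            fit_pca_basis(self._ca_traj(coords), n_components=11)


class TestSchemaAndExtraction:
    def test_gb1_schema_has_294_labels(self):
        assert len(gb1_schema()) == 294

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            FeatureSchema((FeatureEntry("a", "rmsf", 1), FeatureEntry("a", "rmsf", 2)))

    def test_pca_weight_with_residue_rejected(self):
        with pytest.raises(ValueError):
            FeatureSchema((FeatureEntry("p", "pca_weight", 3),))

    def test_vector_length_matches_schema(self, toy_protein, dynamics_model):
        t = simulate_trajectory(toy_protein, None, dynamics_model, 120, seed=11)
        schema = by_residue_schema(("rmsf",), toy_protein.n_residues)
        vec = extract_features(t, schema)
        assert vec.shape == (toy_protein.n_residues,)

    def test_extraction_is_deterministic(self, toy_protein, dynamics_model):
        t = simulate_trajectory(toy_protein, None, dynamics_model, 100, seed=12)
        schema = by_residue_schema(("rmsf", "ks_hbond"), toy_protein.n_residues)
        assert np.array_equal(extract_features(t, schema), extract_features(t, schema))

    def test_unregistered_family_raises(self, toy_protein, dynamics_model):
        t = simulate_trajectory(toy_protein, None, dynamics_model, 50, seed=13)
        schema = FeatureSchema((FeatureEntry("x", "mystery", 1),))
        with pytest.raises(ValueError, match="mystery"):
            extract_features(t, schema)

    def test_pca_family_needs_basis(self, toy_protein, dynamics_model):
        t = simulate_trajectory(toy_protein, None, dynamics_model, 50, seed=14)
        schema = by_residue_schema((), toy_protein.n_residues, n_pca=3)
        with pytest.raises(ValueError, match="basis"):
            extract_features(t, schema)

    def test_schema_json_round_trip(self, tmp_path):
        schema = gb1_schema()
        path = tmp_path / "schema.json"
        schema.to_json(path)
        assert FeatureSchema.from_json(path) == schema
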