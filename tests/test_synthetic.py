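import numpy as np
import pytest

from qdpr.features import compute_rmsf, discard_equilibration
from qdpr.sequences import parse_mutation_string
from qdpr.synthetic import (
    DynamicsModel,
    GroundTruthConfig,
    PoolSpec,
    default_ground_truth,
    default_synthetic_schema,
    make_landscape,
    make_toy_protein,
    simulate_trajectory,
)


class TestToyProtein:
    def test_residue_count_and_pdb_records(self, toy_protein, tmp_path):
        assert toy_protein.n_residues == 24
        path = tmp_path / "toy.pdb"
        toy_protein.to_pdb(path)
        ca_lines = [l for l in path.read_text().splitlines()
                    if l.startswith("ATOM") and l[12:16].strip() == "CA"]
        assert len(ca_lines) == 24

    def test_same_seed_identical_geometry(self):
        a = make_toy_protein(20, seed=3)
        b = make_toy_protein(20, seed=3)
        assert a.sequence == b.sequence
        assert np.array_equal(a.ca_coords, b.ca_coords)

    def test_bonded_ca_distances(self, toy_protein):
        d = np.linalg.norm(np.diff(toy_protein.ca_coords, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.1)

    def test_contact_graph_connected(self, toy_protein):
        import networkx as nx

        g = nx.Graph(list(toy_protein.contacts))
        assert nx.is_connected(g)
        assert g.number_of_nodes() == toy_protein.n_residues

    def test_size_bounds(self):
        with pytest.raises(ValueError):
            make_toy_protein(5)

    def test_pdb_parses_in_biopython(self, toy_protein, tmp_path):
        from Bio.PDB import PDBParser

        path = tmp_path / "toy.pdb"
        toy_protein.to_pdb(path)
        structure = PDBParser(QUIET=True).get_structure("t", path)
        assert len(list(structure.get_residues())) == 24


class TestDynamicsModel:
    def test_kirchhoff_symmetric_psd(self, toy_protein, dynamics_model):
        g = dynamics_model.kirchhoff()
        assert np.allclose(g, g.T)
        assert np.linalg.eigvalsh(g).min() > -1e-9

    def test_sampled_msf_matches_analytic(self, toy_protein, dynamics_model):
        """GNM consistency: sampled RMSF tracks the closed-form profile
        (rigid-body-projected covariance diagonal), r >= 0.95 at 5,000
        frames."""
        traj = simulate_trajectory(toy_protein, None, dynamics_model,
                                   n_frames=5000, seed=2)
        sampled = compute_rmsf(traj)
        analytic = dynamics_model.analytic_rmsf(superposed=True)
        assert np.corrcoef(sampled, analytic)[0, 1] >= 0.95
        # raw pseudo-inverse diagonal is close but biased by superposition
        raw = dynamics_model.analytic_rmsf()
        assert np.corrcoef(sampled, raw)[0, 1] >= 0.9

    def test_stiffer_springs_lower_rmsf(self, toy_protein):
        means = []
        for k in (0.5, 1.0, 2.0):
            m = DynamicsModel(toy_protein, spring_constant=k, tether_spring=k)
            means.append(m.analytic_rmsf().mean())
        assert means[0] > means[1] > means[2]

    def test_mutation_effect_is_local(self, toy_protein, dynamics_model):
        pos = 12
        wt = toy_protein.sequence[pos - 1]
        mut = "D" if wt != "D" else "I"
        v = parse_mutation_string(f"{wt}{pos}{mut}", toy_protein.sequence)
        delta = np.abs(dynamics_model.analytic_rmsf(v.sequence)
                       - dynamics_model.analytic_rmsf())
        assert np.argmax(delta) == pos - 1

    def test_disconnected_graph_rejected(self):
        protein = make_toy_protein(20, seed=4)
        broken = protein.__class__(
            sequence=protein.sequence,
            backbone=protein.backbone,
            contacts=tuple((i, j) for i, j in protein.contacts
                           if not (i < 10 <= j)),
            ss=protein.ss,
        )
        model = DynamicsModel(broken, tether_spring=0.0)
        with pytest.raises(ValueError, match="zero modes"):
            model.covariance()

    def test_trajectory_segments_partition(self, toy_protein, dynamics_model):
        t = simulate_trajectory(toy_protein, None, dynamics_model, 101, seed=5,
                                n_segments=2)
        assert t.segments[0][0] == 0 and t.segments[-1][1] == 101


@pytest.fixture(scope="module")
def landscape(toy_protein, dynamics_model):
    truth = default_ground_truth(toy_protein)
    schema = default_synthetic_schema(toy_protein.n_residues, n_pca=4)
    return truth, make_landscape(
        toy_protein, dynamics_model, truth,
        PoolSpec(n_variants=40, max_mutations=2), seed=1, n_frames=120,
        schema=schema,
    )


class TestLandscape:

    def test_deterministic_given_seed(self, toy_protein, dynamics_model, landscape):
        truth, (pool, table, basis, rec) = landscape
        pool2, table2, _, _ = make_landscape(
            toy_protein, dynamics_model, truth,
            PoolSpec(n_variants=40, max_mutations=2), seed=1, n_frames=120,
            schema=table.schema,
        )
        assert pool.labels == pool2.labels
        assert np.array_equal(table.values.to_numpy(), table2.values.to_numpy())

    def test_noiseless_labels_are_function_of_features(self, toy_protein,
                                                       dynamics_model):
        truth = GroundTruthConfig(
            targets=(("rmsf", 8, 1.0), ("rmsf", 17, 1.0)), epistasis=(),
            noise_sigma=0.0,
        )
        schema = default_synthetic_schema(toy_protein.n_residues, n_pca=0)
        pool, table, _, rec = make_landscape(
            toy_protein, dynamics_model, truth,
            PoolSpec(n_variants=25, max_mutations=2), seed=2, n_frames=100,
            schema=schema,
        )
        wt = np.array([rec["wt_features"][f] for f in schema.feature_ids])
        feats = table.values.loc[list(pool.ids)].to_numpy()
        z = (feats[:, [7, 16]] - wt[[7, 16]]) / np.array(rec["target_scales"])
        assert np.allclose(z.sum(axis=1), pool.label_array(), atol=1e-10)

    def test_epistatic_nonadditivity(self, toy_protein, dynamics_model):
        """With the product term on, a double mutant's noiseless label
        differs from the sum of its singles' labels."""
        truth = default_ground_truth(toy_protein, noise_sigma=0.0)
        r1, r2 = truth.targets[0][1], truth.targets[1][1]
        schema = default_synthetic_schema(toy_protein.n_residues, n_pca=0)
        seq = toy_protein.sequence

        def label_of(mutstr, seed):
            from qdpr.synthetic import extract_features, _truth_fitness_batch

            v = parse_mutation_string(mutstr, seq)
            traj = simulate_trajectory(toy_protein, v, dynamics_model, 400, seed=seed)
            return extract_features(traj, schema)

        wt_feats = label_of("", 10)
        m1 = f"{seq[r1 - 1]}{r1}D"
        m2 = f"{seq[r2 - 1]}{r2}E"
        from qdpr.synthetic import _truth_fitness_batch

        scales = np.array([0.02, 0.02])
        feats = np.stack([label_of(m1, 11), label_of(m2, 12),
                          label_of(f"{m1},{m2}", 13)])
        f1, f2, f12 = _truth_fitness_batch(feats, wt_feats, schema, truth, scales)
        assert abs(f12 - (f1 + f2)) > 0.3

    def test_mutation_count_distribution_in_bounds(self, landscape):
        truth, (pool, *_rest) = landscape
        counts = {pool.n_mutations(v) for v in pool.ids}
        assert counts <= {1, 2}
        assert len(counts) == 2

    def test_oversized_single_mutant_pool_rejected(self, toy_protein,
                                                   dynamics_model):
        truth = default_ground_truth(toy_protein)
        with pytest.raises(ValueError):
            make_landscape(toy_protein, dynamics_model, truth,
                           PoolSpec(n_variants=10_000, min_mutations=1,
                                    max_mutations=1), seed=3, n_frames=50)

    def test_default_targets_are_mid_helix(self, toy_protein):
        truth = default_ground_truth(toy_protein)
        (r1, r2) = truth.targets[0][1], truth.targets[1][1]
        assert toy_protein.ss[r1 - 1] == "H" and toy_protein.ss[r2 - 1] == "H"
        assert r2 - r1 > 4
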