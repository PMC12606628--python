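import numpy as np
import pytest

from qdpr.campaign import (
    CampaignConfig,
    CampaignState,
    LabeledPool,
    OracleStrategy,
    RandomStrategy,
    evaluate_campaigns,
    ndcg,
    run_campaign,
    run_round,
)
from qdpr.sequences import parse_mutation_string

REF = "ACDEFGHIKLMN"


def _pool(labels, seed=0):
    """Pool of single mutants with the given labels."""
    rng = np.random.default_rng(seed)
    variants, labs = {}, {}
    positions = rng.permutation(len(REF))
    for k, lab in enumerate(labels):
        p = int(positions[k % len(REF)]) + 1
        wt = REF[p - 1]
        mut = "Y" if wt != "Y" else "W"
        vid = f"v{k:03d}"
        variants[vid] = parse_mutation_string(f"{wt}{p}{mut}", REF)
        labs[vid] = float(lab)
    return LabeledPool(variants=variants, labels=labs)


class TestNDCG:
    def test_perfect_ordering_is_one(self):
        labels = np.array([5.0, 3.0, 1.0, 0.5])
        assert ndcg(labels, labels) == pytest.approx(1.0)

    def test_worked_three_item_example(self):
        # labels (3,2,1) predicted in reversed order: gains (2,1,0);
        # DCG = 0/1 + 1/log2(3) + 2/2; ideal = 2/1 + 1/log2(3) + 0
        value = ndcg(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0]))
        dcg = 1 / np.log2(3) + 1.0
        ideal = 2.0 + 1 / np.log2(3)
        assert value == pytest.approx(dcg / ideal, abs=1e-6)
        assert value == pytest.approx(0.6199, abs=1e-4)

    def test_single_item_is_one(self):
        assert ndcg([0.3], [7.0]) == 1.0

    def test_all_equal_labels_defined_as_one(self):
        assert ndcg([3.0, 1.0, 2.0], [4.0, 4.0, 4.0]) == 1.0

    def test_all_tied_scores_average_over_orderings(self):
        labels = np.array([3.0, 2.0, 1.0])
        tied = ndcg(np.zeros(3), labels)
        # expected DCG with mean gain at every position
        gains = labels - labels.min()
        discounts = 1 / np.log2(np.arange(3) + 2)
        expected = gains.mean() * discounts.sum() / (np.sort(gains)[::-1] @ discounts)
        assert tied == pytest.approx(expected)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            scores = rng.normal(size=10)
            labels = rng.normal(size=10)
            v = ndcg(scores, labels)
            assert 0 < v <= 1


class TestRounds:
    def test_round_zero_is_seeded_random(self):
        pool = _pool(np.arange(30.0))
        picks = []
        for _ in range(2):
            state = CampaignState()
            run_round(state, pool, RandomStrategy(np.random.default_rng(5)), 8,
                      np.random.default_rng(5))
            picks.append(state.selected_rounds[0])
        assert picks[0] == picks[1]
        assert len(picks[0]) == 8

    def test_oracle_round_one_contains_pool_maximum(self):
        pool = _pool(np.arange(30.0))
        rng = np.random.default_rng(1)
        state = run_campaign(pool, OracleStrategy(), batch_size=8, n_rounds=1, rng=rng)
        best = max(pool.labels, key=pool.labels.get)
        assert best in state.selected_rounds[1]

    def test_training_set_grows_by_batch(self):
        pool = _pool(np.arange(40.0))
        state = run_campaign(pool, OracleStrategy(), batch_size=8, n_rounds=3,
                             rng=np.random.default_rng(2))
        for r, rec in enumerate(state.metrics):
            assert rec["n_train"] == (r + 1) * 8

    def test_no_reselection_across_rounds(self):
        pool = _pool(np.arange(40.0))
        state = run_campaign(pool, OracleStrategy(), batch_size=8, n_rounds=4,
                             rng=np.random.default_rng(3))
        ids = state.selected_ids
        assert len(ids) == len(set(ids))

    def test_pool_exhaustion_terminates_cleanly(self):
        pool = _pool(np.arange(10.0))
        state = run_campaign(pool, OracleStrategy(), batch_size=8, n_rounds=5,
                             rng=np.random.default_rng(4))
        assert sorted(state.selected_ids) == sorted(pool.ids)

    def test_mutated_residues_tracks_training_set(self):
        pool = _pool(np.arange(12.0))
        state = run_campaign(pool, OracleStrategy(), batch_size=4, n_rounds=1,
                             rng=np.random.default_rng(5))
        expected = {
            m.position for vid in state.selected_ids
            for m in pool.variants[vid].mutations
        }
        assert state.mutated_residues(pool) == frozenset(expected)


class TestEvaluateCampaigns:
    def test_oracle_median_max_flat_at_pool_maximum(self):
        pool = _pool(np.arange(60.0))
        cfg = CampaignConfig(batch_size=8, n_rounds=3, n_campaigns=5, seed=1)
        _, summary = evaluate_campaigns(pool, lambda rng: OracleStrategy(), cfg)
        from_round1 = summary[summary["round"] >= 1]["median_max_label"]
        assert (from_round1 == 59.0).all()

    def test_random_round_max_matches_order_statistics(self):
        """Median of the running max under random selection agrees with a
        direct Monte-Carlo simulation of drawing without replacement."""
        n, batch, rounds = 200, 8, 3
        labels = np.arange(float(n))
        pool = _pool(labels, seed=6)
        cfg = CampaignConfig(batch_size=batch, n_rounds=rounds, n_campaigns=60, seed=2)
        tidy, summary = evaluate_campaigns(pool, lambda rng: RandomStrategy(rng), cfg)
        rng = np.random.default_rng(3)
        sims = np.array([
            [np.max(rng.choice(labels, size=(r + 1) * batch, replace=False))
             for r in range(rounds + 1)]
            for _ in range(10_000)
        ])
        expected = np.median(sims, axis=0)
        observed = summary.sort_values("round")["median_max_label"].to_numpy()
        # discrete order statistics: allow a few label ranks of slack
        assert np.abs(observed - expected).max() <= 6.0

    def test_random_ndcg_does_not_trend_upward(self):
        pool = _pool(np.random.default_rng(7).normal(size=80), seed=8)
        cfg = CampaignConfig(batch_size=8, n_rounds=4, n_campaigns=30, seed=4)
        _, summary = evaluate_campaigns(pool, lambda rng: RandomStrategy(rng), cfg)
        vals = summary[summary["round"] >= 1]["mean_ndcg"].to_numpy()
        sems = summary[summary["round"] >= 1]["sem_ndcg"].to_numpy()
        assert vals[-1] - vals[0] < 3 * np.hypot(sems[0], sems[-1])

    def test_mutation_count_stratification_present(self):
        pool = _pool(np.arange(40.0), seed=9)
        cfg = CampaignConfig(batch_size=8, n_rounds=1, n_campaigns=3, seed=5)
        _, summary = evaluate_campaigns(pool, lambda rng: OracleStrategy(), cfg)
        assert any(c.startswith("mean_ndcg_mut") for c in summary.columns)


class TestPoolIO:
    def test_csv_round_trip(self, tmp_path):
        pool = _pool(np.arange(10.0))
        path = tmp_path / "pool.csv"
        pool.to_csv(path)
        back = LabeledPool.from_csv(path, REF)
        assert back.ids == pool.ids
        assert back.labels == pool.labels
        assert all(back.variants[i] == pool.variants[i] for i in pool.ids)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("variant_id,mutations,label\nv0,A1Y,1.0\nv1,Z9Q,2.0\n")
        with pytest.raises(ValueError, match="line 3"):
            LabeledPool.from_csv(path, REF)

    def test_nonfinite_label_rejected(self):
        with pytest.raises(ValueError):
            _pool([1.0, np.inf])
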