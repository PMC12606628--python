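"""Simulated ML-guided protein-engineering campaigns over a labeled pool.

A campaign is a sequence of selection rounds against a pool of variants with
known property labels (standing in for running experiments). Round zero is a
uniform-random draw; in each later round the strategy is retrained on every
label collected so far, scores the not-yet-selected pool, and the top
``batch_size`` scorers are selected. Metrics recorded per round: NDCG and
Spearman rank correlation of the model scores across the pool and the best
label found so far.

NDCG uses linear, min-shifted gains (gain_i = label_i - min(label)) with the
standard 1/log2(rank + 1) discount; tied predicted scores contribute the
mean gain of their tie group at each of the group's positions, which equals
the expectation over random tie orderings.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .sequences import Variant, encode_variants, parse_mutation_string

__all__ = [
    "LabeledPool",
    "CampaignConfig",
    "CampaignState",
    "ndcg",
    "run_round",
    "run_campaign",
    "evaluate_campaigns",
    "RandomStrategy",
    "OracleStrategy",
    "QDPRStrategy",
]


@dataclasses.dataclass
class LabeledPool:
    """A labeled variant pool: id -> (variant, label)."""

    variants: dict[str, Variant]
    labels: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.variants) != set(self.labels):
            raise ValueError("variants and labels must share ids")
        bad = [k for k, v in self.labels.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite labels for {bad[:3]}")
        self.ids = tuple(sorted(self.variants))

    def __len__(self) -> int:
        return len(self.ids)

    def n_mutations(self, vid: str) -> int:
        return self.variants[vid].n_mutations

    def label_array(self, ids=None) -> np.ndarray:
        ids = self.ids if ids is None else ids
        return np.array([self.labels[i] for i in ids])

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "variant_id": list(self.ids),
                "mutations": [str(self.variants[i]) for i in self.ids],
                "label": [self.labels[i] for i in self.ids],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reference: str) -> "LabeledPool":
        df = pd.read_csv(path, dtype={"mutations": str})
        required = {"variant_id", "mutations", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"pool CSV needs columns {sorted(required)}")
        variants, labels = {}, {}
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            muts = "" if pd.isna(row.mutations) else row.mutations
            try:
                variants[row.variant_id] = parse_mutation_string(muts, reference)
                labels[row.variant_id] = float(row.label)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"line {row_no}: {exc}") from exc
        return cls(variants=variants, labels=labels)


@dataclasses.dataclass(frozen=True)
class CampaignConfig:
    batch_size: int = 8
    n_rounds: int = 5
    n_campaigns: int = 100
    seed: int = 0
    include_selected_in_ndcg: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.n_campaigns < 1 or self.n_rounds < 0:
            raise ValueError("invalid campaign configuration")


@dataclasses.dataclass
class CampaignState:
    """Selections and metric history of a single campaign."""

    selected_rounds: list[list[str]] = dataclasses.field(default_factory=list)
    metrics: list[dict] = dataclasses.field(default_factory=list)

    @property
    def selected_ids(self) -> list[str]:
        return [i for rnd in self.selected_rounds for i in rnd]

    def mutated_residues(self, pool: "LabeledPool") -> frozenset[int]:
        """Residue positions mutated in any selected (training) variant."""
        res = set()
        for vid in self.selected_ids:
            res.update(m.position for m in pool.variants[vid].mutations)
        return frozenset(res)


def ndcg(scores, labels) -> float:
    """Normalized discounted cumulative gain of a predicted ordering."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    if scores.size == 0 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned and non-empty")
    gains = labels - labels.min()
    if gains.max() == 0:  # all labels equal: any ordering is ideal
        return 1.0
    discounts = 1.0 / np.log2(np.arange(len(labels)) + 2.0)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_gains = gains[order]
    # average gains within predicted-score tie groups (expected DCG over ties)
    dcg = 0.0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and sorted_scores[j] == sorted_scores[i]:
            j += 1
        dcg += sorted_gains[i:j].mean() * discounts[i:j].sum()
        i = j
    ideal = float(np.sort(gains)[::-1] @ discounts)
    return float(dcg / ideal)


class RandomStrategy:
    """Uniform-random selection baseline; scores are i.i.d. uniforms."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def fit(self, pool: LabeledPool, train_ids: list[str]) -> None:
        pass

    def score(self, pool: LabeledPool, ids) -> np.ndarray:
        return self.rng.random(len(ids))


class OracleStrategy:
    """Upper bound: scores are the true labels."""

    def fit(self, pool: LabeledPool, train_ids: list[str]) -> None:
        pass

    def score(self, pool: LabeledPool, ids) -> np.ndarray:
        return pool.label_array(ids)


class QDPRStrategy:
    """The full pipeline strategy: fixed pre-trained feature surrogates, a
    property surrogate and score predictor retrained each round on the
    labels collected so far."""

    def __init__(
        self,
        surrogates: dict,
        schema,
        property_surrogate_factory: Callable,
        predictor_factory: Callable,
    ):
        self.surrogates = surrogates
        self.schema = schema
        self.property_surrogate_factory = property_surrogate_factory
        self.predictor_factory = predictor_factory
        self.scorer_ = None
        self._cache: dict[str, np.ndarray] = {}

    def _encode(self, pool: LabeledPool, ids) -> np.ndarray:
        missing = [i for i in ids if i not in self._cache]
        if missing:
            enc = encode_variants([pool.variants[i] for i in missing])
            for k, i in enumerate(missing):
                self._cache[i] = enc[k]
        return np.stack([self._cache[i] for i in ids])

    def fit(self, pool: LabeledPool, train_ids: list[str]) -> None:
        from .score import QDPRScorer

        encodings = self._encode(pool, train_ids)
        labels = pool.label_array(train_ids)
        self.scorer_ = QDPRScorer.fit(
            self.surrogates,
            self.schema,
            encodings,
            labels,
            self.property_surrogate_factory,
            self.predictor_factory,
            stats_encodings=self._encode(pool, list(pool.ids)),
        )

    def score(self, pool: LabeledPool, ids) -> np.ndarray:
        if self.scorer_ is None:
            raise RuntimeError("strategy not fitted")
        return self.scorer_.score(self._encode(pool, ids))

    def feature_predictions(self, pool: LabeledPool, ids) -> np.ndarray:
        from .surrogates import predict_feature_matrix

        return predict_feature_matrix(
            self.surrogates, self._encode(pool, ids), self.schema
        )


def run_round(
    state: CampaignState,
    pool: LabeledPool,
    strategy,
    batch_size: int,
    rng: np.random.Generator,
    include_selected_in_ndcg: bool = True,
) -> CampaignState:
    """Execute one selection round, mutating and returning ``state``.

    Round zero (empty state) selects uniformly at random; later rounds fit
    the strategy on the cumulative training set and take the top scorers,
    ties broken by stable id order.
    """
    selected = set(state.selected_ids)
    remaining = [i for i in pool.ids if i not in selected]
    if not remaining:
        return state
    round_no = len(state.selected_rounds)
    record: dict = {"round": round_no, "ndcg": np.nan, "spearman": np.nan}
    if round_no == 0:
        pick_idx = rng.choice(len(remaining), size=min(batch_size, len(remaining)), replace=False)
        picks = [remaining[int(i)] for i in sorted(pick_idx)]
    else:
        strategy.fit(pool, state.selected_ids)
        eval_ids = list(pool.ids) if include_selected_in_ndcg else remaining
        eval_scores = strategy.score(pool, eval_ids)
        eval_labels = pool.label_array(eval_ids)
        record["ndcg"] = ndcg(eval_scores, eval_labels)
        rem_scores = (
            eval_scores[[eval_ids.index(i) for i in remaining]]
            if include_selected_in_ndcg
            else eval_scores
        )
        if len(remaining) > 2:
            record["spearman"] = float(
                spearmanr(rem_scores, pool.label_array(remaining)).statistic
            )
        order = np.lexsort((remaining, -rem_scores))  # score desc, id asc on ties
        picks = [remaining[int(i)] for i in order[: min(batch_size, len(remaining))]]
    state.selected_rounds.append(picks)
    all_labels = pool.label_array(state.selected_ids)
    record["max_label"] = float(all_labels.max())
    record["n_train"] = len(state.selected_ids)
    state.metrics.append(record)
    return state


def run_campaign(
    pool: LabeledPool,
    strategy,
    batch_size: int,
    n_rounds: int,
    rng: np.random.Generator,
    include_selected_in_ndcg: bool = True,
) -> CampaignState:
    """Run round 0 plus ``n_rounds`` guided rounds (stops if exhausted)."""
    state = CampaignState()
    for _ in range(n_rounds + 1):
        if len(state.selected_ids) >= len(pool):
            break
        run_round(state, pool, strategy, batch_size, rng, include_selected_in_ndcg)
    return state


def evaluate_campaigns(
    pool: LabeledPool,
    strategy_factory: Callable[[np.random.Generator], object],
    config: CampaignConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run many independent campaigns and aggregate their metric curves.

    Returns ``(tidy, summary)``: per-campaign per-round records, and a
    per-round summary with mean NDCG +/- SEM, the median of each campaign's
    highest label so far +/- SEM, and per-mutation-count NDCG columns.
    """
    rows = []
    sub_pools = _mutation_count_subsets(pool)
    for c in range(config.n_campaigns):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % 2**31, c])
        )
        strategy = strategy_factory(rng)
        state = CampaignState()
        for _ in range(config.n_rounds + 1):
            if len(state.selected_ids) >= len(pool):
                break
            run_round(
                state, pool, strategy, config.batch_size, rng,
                config.include_selected_in_ndcg,
            )
            rec = dict(state.metrics[-1])
            rec["campaign"] = c
            if rec["round"] > 0 and sub_pools:
                for n_mut, ids in sub_pools.items():
                    scores = strategy.score(pool, ids)
                    rec[f"ndcg_mut{n_mut}"] = ndcg(scores, pool.label_array(ids))
            rows.append(rec)
    tidy = pd.DataFrame(rows)

    def sem(x):
        x = np.asarray(x, float)
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    agg = {
        "mean_ndcg": ("ndcg", "mean"),
        "sem_ndcg": ("ndcg", sem),
        "median_max_label": ("max_label", "median"),
        "sem_max_label": ("max_label", sem),
    }
    for col in tidy.columns:
        if col.startswith("ndcg_mut"):
            agg[f"mean_{col}"] = (col, "mean")
    summary = tidy.groupby("round").agg(**agg).reset_index()
    return tidy, summary


def _mutation_count_subsets(pool: LabeledPool, min_size: int = 8) -> dict[int, list[str]]:
    by_count: dict[int, list[str]] = {}
    for vid in pool.ids:
        by_count.setdefault(pool.n_mutations(vid), []).append(vid)
    return {k: v for k, v in by_count.items() if len(v) >= min_size}
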