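"""High-level wiring: train surrogates for a pool and build campaign
strategies.

Desk-scale default network sizes are used here (16-channel convolutions,
narrow dense heads, patience 60, single restart) so a full multi-campaign
evaluation runs in minutes on one CPU; every size is overridable.
"""

from __future__ import annotations

import numpy as np

from .campaign import LabeledPool, OracleStrategy, QDPRStrategy, RandomStrategy
from .score import ScorePredictor
from .sequences import encode_variants
from .surrogates import PropertySurrogate, train_family_surrogates

__all__ = [
    "SMALL_SURROGATE_KWARGS",
    "train_surrogates_for_pool",
    "qdpr_strategy_factory",
    "make_strategy_factory",
]

# compact-network defaults for interactive / desk-scale runs
SMALL_SURROGATE_KWARGS = dict(
    conv_channels=(16, 16),
    dense_width=32,
    max_epochs=400,
    patience=60,
    restarts=1,
    batch_size=32,
)

SMALL_PROPERTY_KWARGS = dict(
    conv_channels=(16,),
    dense_width=16,
    max_epochs=300,
    patience=60,
    restarts=1,
    batch_size=8,
)

# few-shot preset for the per-round score network: a faster learning rate
# with weight decay so the 400 fixed epochs reach a shrunken fit from a
# handful of labels (the class defaults keep the canonical constants)
SMALL_SCORE_KWARGS = dict(learning_rate=1e-2, weight_decay=0.3)


def train_surrogates_for_pool(
    pool: LabeledPool,
    feature_table,
    random_state: int = 0,
    **surrogate_kwargs,
):
    """Fit per-family surrogates on the pool variants present in the table."""
    kwargs = {**SMALL_SURROGATE_KWARGS, **surrogate_kwargs}
    ids = list(feature_table.values.index)
    missing = [i for i in ids if i not in pool.variants]
    if missing:
        raise ValueError(f"feature rows without pool variants: {missing[:3]}")
    encodings = encode_variants([pool.variants[i] for i in ids])
    return train_family_surrogates(
        encodings, feature_table, random_state=random_state, **kwargs
    )


def qdpr_strategy_factory(
    surrogates: dict,
    schema,
    property_kwargs: dict | None = None,
    predictor_kwargs: dict | None = None,
):
    """Campaign strategy factory for the full QDPR pipeline.

    The per-round property surrogate and score predictor draw their weight
    seeds from the campaign RNG, so campaigns are independent yet
    reproducible from one seed.
    """
    prop_kwargs = {**SMALL_PROPERTY_KWARGS, **(property_kwargs or {})}
    pred_kwargs = {**SMALL_SCORE_KWARGS, **(predictor_kwargs or {})}

    def factory(rng: np.random.Generator):
        return QDPRStrategy(
            surrogates,
            schema,
            property_surrogate_factory=lambda: PropertySurrogate(
                **prop_kwargs, random_state=int(rng.integers(2**31))
            ),
            predictor_factory=lambda: ScorePredictor(
                **pred_kwargs, random_state=int(rng.integers(2**31))
            ),
        )

    return factory


def make_strategy_factory(
    name: str,
    pool: LabeledPool,
    features_path=None,
    schema_path=None,
    seed: int = 0,
    surrogates: dict | None = None,
    schema=None,
):
    """Build a strategy factory by name ('random', 'oracle', 'qdpr')."""
    if name == "random":
        return lambda rng: RandomStrategy(rng)
    if name == "oracle":
        return lambda rng: OracleStrategy()
    if name != "qdpr":
        raise ValueError(f"unknown strategy {name!r}")
    if surrogates is None:
        from .features import FeatureTable
        from .io import derive_seed

        if features_path is None or schema_path is None:
            raise ValueError("qdpr strategy needs a feature table and schema")
        table = FeatureTable.from_csv(features_path, schema_path)
        schema = table.schema
        surrogates = train_surrogates_for_pool(
            pool, table, random_state=derive_seed(seed, "surrogates")
        )
    return qdpr_strategy_factory(surrogates, schema)
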