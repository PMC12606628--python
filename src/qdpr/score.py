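"""The downstream score predictor.

A deliberately small network — eight densely connected units with a leaky
rectified-linear activation followed by a single linear output — maps the
concatenated upstream predictions (every feature family plus the
feature-level property prediction) to a property score. It is trained on all
available experimental labels for a fixed 400 epochs (no early stopping)
with learning rate 1e-4 and batch size 8. Input columns are standardized by
training-set statistics before the network, since feature families live on
wildly different scales.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .nn import Dense, LeakyReLU, Network, train_network
from .surrogates import predict_feature_matrix

__all__ = ["ScorePredictor", "assemble_inputs", "QDPRScorer", "score_variants"]


class ScorePredictor(BaseEstimator, RegressorMixin):
    """Eight-unit hidden layer, single linear output, fixed-epoch training."""

    def __init__(
        self,
        hidden_width=8,
        epochs=400,
        learning_rate=1e-4,
        batch_size=8,
        leaky_slope=0.3,
        weight_decay=0.0,
        standardize_labels=True,
        zero_init_output=True,
        random_state=0,
    ):
        self.hidden_width = hidden_width
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.leaky_slope = leaky_slope
        self.weight_decay = weight_decay
        self.standardize_labels = standardize_labels
        self.zero_init_output = zero_init_output
        self.random_state = random_state

    def fit(self, x, y, input_stats=None):
        """Fit on assembled inputs.

        ``input_stats`` optionally supplies (mean, std) for the per-column
        input standardization — e.g. statistics over the full candidate pool,
        which are label-free and far more stable than the statistics of a
        handful of training rows.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float).reshape(-1, 1)
        if x.ndim != 2 or len(x) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("inputs and labels must be finite")
        if len(x) < self.batch_size:
            warnings.warn(
                f"{len(x)} samples < batch size {self.batch_size}; using full batches"
            )
        if input_stats is None:
            mean, std = x.mean(axis=0), x.std(axis=0)
        else:
            mean, std = (np.asarray(v, float) for v in input_stats)
        self.mean_ = mean
        self.std_ = np.where(std > 0, std, 1.0)
        xs = (x - self.mean_) / self.std_
        if self.standardize_labels:
            self.y_mean_ = float(y.mean())
            y_std = float(y.std())
            self.y_std_ = y_std if y_std > 0 else 1.0
        else:
            self.y_mean_, self.y_std_ = 0.0, 1.0
        ys = (y - self.y_mean_) / self.y_std_
        rng = np.random.default_rng(self.random_state)
        self.network_ = Network(
            [
                Dense(x.shape[1], self.hidden_width, rng),
                LeakyReLU(self.leaky_slope),
                Dense(self.hidden_width, 1, rng),
            ]
        )
        if self.zero_init_output:
            # start at the mean prediction: the output layer then learns a
            # shrunken regression on the hidden projections first
            self.network_.layers[-1].w[...] = 0.0
            self.network_.layers[-1].b[...] = 0.0
        self.history_ = train_network(
            self.network_,
            xs,
            ys,
            None,
            None,
            max_epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            patience=None,
            rng=rng,
            weight_decay=self.weight_decay,
        )
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, x):
        x = np.asarray(x, float)
        if x.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        xs = (x - self.mean_) / self.std_
        return self.network_.forward(xs)[:, 0] * self.y_std_ + self.y_mean_


def assemble_inputs(
    encodings: np.ndarray,
    surrogates: dict,
    schema,
    property_surrogate=None,
    input_spec: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Concatenate upstream predictions into the score-network input matrix.

    Columns follow ``input_spec`` (default: schema family order, then the
    property surrogate's single column last).
    """
    families = schema.families
    missing = [f for f in families if f not in surrogates]
    if missing:
        raise ValueError(f"missing surrogates for families: {missing}")
    spec = tuple(input_spec) if input_spec else families + (
        ("property",) if property_surrogate is not None else ()
    )
    blocks = []
    feature_matrix = predict_feature_matrix(surrogates, encodings, schema)
    for name in spec:
        if name == "property":
            if property_surrogate is None:
                raise ValueError("input spec names 'property' but none was given")
            blocks.append(property_surrogate.predict(encodings).reshape(len(encodings), 1))
        else:
            blocks.append(feature_matrix[:, schema.family_slice(name)])
    return np.concatenate(blocks, axis=1)


class QDPRScorer:
    """Bundles trained feature surrogates with the property surrogate and
    score predictor; scoring is a pure function of sequence encodings and
    touches no trajectory data."""

    def __init__(self, surrogates: dict, schema, property_surrogate, predictor):
        self.surrogates = surrogates
        self.schema = schema
        self.property_surrogate = property_surrogate
        self.predictor = predictor

    @classmethod
    def fit(
        cls,
        surrogates: dict,
        schema,
        encodings: np.ndarray,
        labels: np.ndarray,
        property_surrogate_factory,
        predictor_factory,
        stats_encodings: np.ndarray | None = None,
    ) -> "QDPRScorer":
        """Train the label-dependent halves (property surrogate + score
        network) on the currently labeled variants.

        ``stats_encodings`` (e.g. the full candidate pool) supplies label-free
        input-standardization statistics for the score network; with only a
        few labeled variants the training rows alone estimate column scales
        poorly."""
        prop = property_surrogate_factory()
        prop.fit(encodings, labels)
        inputs = assemble_inputs(encodings, surrogates, schema, prop)
        stats = None
        if stats_encodings is not None:
            pool_inputs = assemble_inputs(stats_encodings, surrogates, schema, prop)
            stats = (pool_inputs.mean(axis=0), pool_inputs.std(axis=0))
        predictor = predictor_factory()
        predictor.fit(inputs, labels, input_stats=stats)
        return cls(surrogates, schema, prop, predictor)

    def score(self, encodings: np.ndarray) -> np.ndarray:
        inputs = assemble_inputs(
            encodings, self.surrogates, self.schema, self.property_surrogate
        )
        return self.predictor.predict(inputs)

    def feature_predictions(self, encodings: np.ndarray) -> np.ndarray:
        return predict_feature_matrix(self.surrogates, encodings, self.schema)


def score_variants(scorer: QDPRScorer, encodings: np.ndarray, variant_ids) -> dict:
    """Map variant_id -> score for a batch of encoded sequences."""
    scores = scorer.score(encodings)
    return dict(zip(variant_ids, scores.tolist()))
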