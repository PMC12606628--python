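"""Sequence-to-feature surrogate networks, sklearn-estimator style.

:class:`FeatureSurrogate` maps encoded sequences (n, L, C) to one feature
family's label vector via a small convolutional network; labels are linearly
rescaled to [0, 1] on the training range before fitting and inverse-scaled at
prediction. Training uses validation-based early stopping (patience 500 by
default, best-epoch weights restored) repeated over independent restarts
(3 by default), keeping the restart with the lowest validation error.

:class:`PropertySurrogate` is the "feature-level" property predictor: the
same protocol with a single output and a validation split of 10% of the
available labels; with fewer than 10 labels it falls back to fixed-epoch
training without validation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin

from .nn import Conv1D, Dense, Flatten, LeakyReLU, Network, train_network

__all__ = [
    "LabelScaler",
    "FeatureSurrogate",
    "PropertySurrogate",
    "train_family_surrogates",
    "predict_feature_matrix",
]


class LabelScaler:
    """Per-label linear [0, 1] rescaling on the training range.

    Constant labels are flagged degenerate: they transform to 0 and
    inverse-transform back to the constant. Out-of-range inputs extrapolate
    linearly (no clipping).
    """

    def fit(self, y: np.ndarray) -> "LabelScaler":
        y = np.asarray(y, float)
        self.min_ = y.min(axis=0)
        self.max_ = y.max(axis=0)
        self.degenerate_ = self.max_ <= self.min_
        self.scale_ = np.where(self.degenerate_, 1.0, self.max_ - self.min_)
        return self

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, float) - self.min_) / self.scale_

    def inverse_transform(self, y: np.ndarray) -> np.ndarray:
        out = np.asarray(y, float) * self.scale_ + self.min_
        if self.degenerate_.any():
            out = np.where(self.degenerate_, self.min_, out)
        return out


def _build_conv_net(
    length: int,
    channels: int,
    n_outputs: int,
    conv_channels: tuple[int, ...],
    kernel_size: int,
    dense_width: int,
    leaky_slope: float,
    rng: np.random.Generator,
) -> Network:
    layers: list = []
    c_in = channels
    for c_out in conv_channels:
        layers += [Conv1D(c_in, c_out, kernel_size, rng), LeakyReLU(leaky_slope)]
        c_in = c_out
    layers.append(Flatten())
    flat = length * c_in
    if dense_width:
        layers += [Dense(flat, dense_width, rng), LeakyReLU(leaky_slope)]
        flat = dense_width
    layers.append(Dense(flat, n_outputs, rng))
    return Network(layers)


class _ConvRegressor(BaseEstimator, RegressorMixin):
    """Shared fit/predict machinery for the surrogate estimators."""

    def __init__(
        self,
        conv_channels=(64, 64),
        kernel_size=5,
        dense_width=128,
        learning_rate=1e-3,
        batch_size=32,
        patience=500,
        restarts=3,
        max_epochs=2000,
        validation_split=0.1,
        leaky_slope=0.3,
        random_state=0,
    ):
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.dense_width = dense_width
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.restarts = restarts
        self.max_epochs = max_epochs
        self.validation_split = validation_split
        self.leaky_slope = leaky_slope
        self.random_state = random_state

    # -- validation-split policy; subclasses override ----------------------
    def _n_validation(self, n: int) -> int:
        if isinstance(self.validation_split, float):
            return int(round(self.validation_split * n))
        return int(self.validation_split)

    def _check_xy(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if y.ndim == 1:
            y = y[:, None]
        if x.ndim != 3:
            raise ValueError("X must be (n_variants, length, channels)")
        if len(x) != len(y):
            raise ValueError("X and y disagree on sample count")
        if not np.isfinite(y).all():
            raise ValueError("labels must be finite")
        if not np.isfinite(x).all():
            raise ValueError("encodings must be finite")
        return x, y

    def fit(self, x, y, channel_spec=None):
        x, y = self._check_xy(x, y)
        n = len(x)
        rng = np.random.default_rng(self.random_state)
        n_val = min(self._n_validation(n), n - 1)
        use_validation = n_val >= 1
        if not use_validation:
            warnings.warn(
                "too few labels for a validation split; training for a fixed "
                f"{self.max_epochs} epochs without early stopping"
            )
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]

        self.scaler_ = LabelScaler().fit(y[train_idx])
        y_s = self.scaler_.transform(y)

        runs = []
        for restart in range(max(1, int(self.restarts))):
            init_rng = np.random.default_rng(
                np.random.SeedSequence([int(self.random_state) % 2**31, restart])
            )
            net = _build_conv_net(
                x.shape[1],
                x.shape[2],
                y.shape[1],
                tuple(self.conv_channels),
                self.kernel_size,
                self.dense_width,
                self.leaky_slope,
                init_rng,
            )
            history = train_network(
                net,
                x[train_idx],
                y_s[train_idx],
                x[val_idx] if use_validation else None,
                y_s[val_idx] if use_validation else None,
                max_epochs=self.max_epochs,
                batch_size=self.batch_size,
                learning_rate=self.learning_rate,
                patience=self.patience if use_validation else None,
                rng=init_rng,
            )
            score = (
                history.get("best_val_mse", np.inf)
                if use_validation
                else history["train_mse"][-1]
            )
            runs.append((score, net, history))

        self.restart_scores_ = [r[0] for r in runs]
        best = int(np.argmin(self.restart_scores_))
        _, self.network_, self.history_ = runs[best]
        self.n_outputs_ = y.shape[1]
        self.input_shape_ = x.shape[1:]
        self.channel_spec_ = tuple(channel_spec) if channel_spec is not None else None
        self.validation_mse_ = self.restart_scores_[best]
        if use_validation:
            pred_val = self._predict_scaled(x[val_idx])
            self.validation_score_ = np.array(
                [
                    pearsonr(pred_val[:, j], y_s[val_idx][:, j]).statistic
                    if np.std(y_s[val_idx][:, j]) > 0 and np.std(pred_val[:, j]) > 0
                    else 0.0
                    for j in range(y.shape[1])
                ]
            )
        else:
            self.validation_score_ = np.full(y.shape[1], np.nan)
        return self

    def _predict_scaled(self, x: np.ndarray) -> np.ndarray:
        out = [self.network_.forward(x[i : i + 512]) for i in range(0, len(x), 512)]
        return np.concatenate(out)

    def predict(self, x, channel_spec=None):
        x = np.asarray(x, float)
        if x.shape[1:] != self.input_shape_:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match training {self.input_shape_}"
            )
        if (
            channel_spec is not None
            and self.channel_spec_ is not None
            and tuple(channel_spec) != self.channel_spec_
        ):
            raise ValueError("channel spec does not match the one used in training")
        return self.scaler_.inverse_transform(self._predict_scaled(x))


class FeatureSurrogate(_ConvRegressor):
    """Surrogate network for one biophysical feature family."""

    def __init__(
        self,
        family="rmsf",
        conv_channels=(64, 64),
        kernel_size=5,
        dense_width=128,
        learning_rate=1e-3,
        batch_size=32,
        patience=500,
        restarts=3,
        max_epochs=2000,
        validation_split=0.1,
        leaky_slope=0.3,
        random_state=0,
    ):
        super().__init__(
            conv_channels=conv_channels,
            kernel_size=kernel_size,
            dense_width=dense_width,
            learning_rate=learning_rate,
            batch_size=batch_size,
            patience=patience,
            restarts=restarts,
            max_epochs=max_epochs,
            validation_split=validation_split,
            leaky_slope=leaky_slope,
            random_state=random_state,
        )
        self.family = family


class PropertySurrogate(_ConvRegressor):
    """Feature-level property predictor: single output, 10% validation."""

    def __init__(
        self,
        conv_channels=(64, 64),
        kernel_size=5,
        dense_width=128,
        learning_rate=1e-3,
        batch_size=8,
        patience=500,
        restarts=3,
        max_epochs=2000,
        leaky_slope=0.3,
        random_state=0,
    ):
        super().__init__(
            conv_channels=conv_channels,
            kernel_size=kernel_size,
            dense_width=dense_width,
            learning_rate=learning_rate,
            batch_size=batch_size,
            patience=patience,
            restarts=restarts,
            max_epochs=max_epochs,
            validation_split=0.1,
            leaky_slope=leaky_slope,
            random_state=random_state,
        )

    def _n_validation(self, n: int) -> int:
        # 10% of the available labels; below 10 labels there is no split and
        # fit() falls back to fixed-epoch training
        if n < 10:
            return 0
        return max(1, int(np.floor(0.1 * n)))

    def fit(self, x, y, channel_spec=None):
        y = np.asarray(y, float)
        if y.ndim != 1 and not (y.ndim == 2 and y.shape[1] == 1):
            raise ValueError("property surrogate is single-output")
        return super().fit(x, y, channel_spec=channel_spec)


def train_family_surrogates(
    encodings: np.ndarray,
    feature_table,
    families: tuple[str, ...] | None = None,
    random_state: int = 0,
    **surrogate_kwargs,
) -> dict[str, FeatureSurrogate]:
    """Fit one :class:`FeatureSurrogate` per family in a feature table.

    ``encodings`` rows must align with the table's variant rows.
    """
    schema = feature_table.schema
    values = feature_table.values.to_numpy()
    families = schema.families if families is None else families
    out = {}
    for k, fam in enumerate(families):
        cols = schema.family_slice(fam)
        est = FeatureSurrogate(
            family=fam, random_state=random_state + k, **surrogate_kwargs
        )
        est.fit(encodings, values[:, cols])
        out[fam] = est
    return out


def predict_feature_matrix(
    surrogates: dict[str, "FeatureSurrogate"],
    encodings: np.ndarray,
    schema,
) -> np.ndarray:
    """Predict the full (n, |schema|) feature matrix in schema order."""
    missing = [f for f in schema.families if f not in surrogates]
    if missing:
        raise ValueError(f"no trained surrogate for families {missing}")
    n = len(encodings)
    out = np.empty((n, len(schema)))
    for fam in schema.families:
        out[:, schema.family_slice(fam)] = surrogates[fam].predict(encodings)
    return out
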