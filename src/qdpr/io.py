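"""File-format plumbing: FASTA references, model checkpoints, run configs,
and deterministic per-module seed derivation."""

from __future__ import annotations

import hashlib
import json

import numpy as np
import yaml

__all__ = [
    "read_fasta",
    "derive_seed",
    "save_estimator",
    "load_estimator",
    "RunConfig",
]


def read_fasta(path) -> tuple[str, str]:
    """Read the first record of a FASTA file -> (id, sequence)."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def derive_seed(global_seed: int, name: str) -> int:
    """Fan one global seed out to a named per-module stream (< 2^31)."""
    digest = hashlib.blake2b(
        f"{int(global_seed)}:{name}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "little") % 2**31


def save_estimator(estimator, path) -> None:
    """Self-describing checkpoint: constructor params + fitted arrays."""
    from .score import ScorePredictor
    from .surrogates import FeatureSurrogate, PropertySurrogate

    kind = type(estimator).__name__
    if kind not in {"FeatureSurrogate", "PropertySurrogate", "ScorePredictor"}:
        raise ValueError(f"cannot checkpoint {kind}")
    arrays = {
        f"w{i}": w for i, w in enumerate(estimator.network_.get_weights())
    }
    meta = {"kind": kind, "params": estimator.get_params()}
    if kind == "ScorePredictor":
        arrays["mean"] = estimator.mean_
        arrays["std"] = estimator.std_
        arrays["y_stats"] = np.array([estimator.y_mean_, estimator.y_std_])
        meta["n_features_in"] = int(estimator.n_features_in_)
    else:
        arrays["scaler_min"] = estimator.scaler_.min_
        arrays["scaler_max"] = estimator.scaler_.max_
        meta["input_shape"] = [int(v) for v in estimator.input_shape_]
        meta["n_outputs"] = int(estimator.n_outputs_)
        if estimator.channel_spec_ is not None:
            meta["channel_spec"] = list(estimator.channel_spec_)
    meta["params"] = _jsonable(meta["params"])
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_estimator(path):
    from .nn import Dense, LeakyReLU, Network
    from .score import ScorePredictor
    from .surrogates import FeatureSurrogate, LabelScaler, PropertySurrogate, _build_conv_net

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    params = meta["params"]
    for key in ("conv_channels",):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    kind = meta["kind"]
    rng = np.random.default_rng(0)
    if kind == "ScorePredictor":
        est = ScorePredictor(**params)
        n_in = meta["n_features_in"]
        est.network_ = Network(
            [
                Dense(n_in, est.hidden_width, rng),
                LeakyReLU(est.leaky_slope),
                Dense(est.hidden_width, 1, rng),
            ]
        )
        est.mean_, est.std_ = arrays["mean"], arrays["std"]
        est.y_mean_, est.y_std_ = (float(v) for v in arrays["y_stats"])
        est.n_features_in_ = n_in
    else:
        cls = FeatureSurrogate if kind == "FeatureSurrogate" else PropertySurrogate
        est = cls(**params)
        length, channels = meta["input_shape"]
        est.network_ = _build_conv_net(
            length,
            channels,
            meta["n_outputs"],
            tuple(est.conv_channels),
            est.kernel_size,
            est.dense_width,
            est.leaky_slope,
            rng,
        )
        est.scaler_ = LabelScaler()
        est.scaler_.min_ = arrays["scaler_min"]
        est.scaler_.max_ = arrays["scaler_max"]
        est.scaler_.degenerate_ = est.scaler_.max_ <= est.scaler_.min_
        est.scaler_.scale_ = np.where(
            est.scaler_.degenerate_, 1.0, est.scaler_.max_ - est.scaler_.min_
        )
        est.input_shape_ = (length, channels)
        est.n_outputs_ = meta["n_outputs"]
        est.channel_spec_ = (
            tuple(meta["channel_spec"]) if "channel_spec" in meta else None
        )
    weights = [arrays[f"w{i}"] for i in range(len([k for k in arrays if k.startswith("w")]))]
    est.network_.set_weights(weights)
    return est


_RUNCONFIG_KEYS = {
    "structure",
    "reference_fasta",
    "trajectories",
    "labels",
    "output_dir",
    "schema",
    "seed",
    "log_level",
    "surrogate",
    "property_surrogate",
    "score",
    "campaign",
    "synthetic",
}


class RunConfig(dict):
    """YAML-backed run configuration; unknown top-level keys are rejected."""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        unknown = set(data) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dict(self), f, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.blake2b(
            json.dumps(dict(self), sort_keys=True, default=str).encode(),
            digest_size=8,
        ).hexdigest()
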