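"""Feed-forward regression from ordinal probabilities to the flicker exponent.

The estimator is trained on the ``D!`` ordinal-pattern probabilities of
flicker-noise series generated over a grid of known spectral exponents
``alpha``; it then assigns to any probability vector an *effective*
exponent ``alpha_e`` — the temporal-correlation strength of the
flicker-noise process whose ordinal statistics the input most resembles.

The network is a single hidden layer:

    X' = f(W X + b),      alpha_e = f'(W' X' + b'),

with tanh hidden activation and identity output, fitted by Adam on mean
squared error with early stopping on a held-out validation split.
Training is delegated to scikit-learn; the fitted weights (and the
feature standardisation) are extracted into a plain :class:`RegressorModel`
so that prediction, serialisation and loading are self-contained.

Ordinal probabilities are scale-invariant, so the model inherits exact
invariance of ``alpha_e`` under monotone affine transforms of the series.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .generators import flicker_noise
from .ordinal import OrdinalConfig, OrdinalDistribution, ordinal_distribution

__all__ = [
    "TrainingSet",
    "RegressorModel",
    "build_training_set",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1

DEFAULT_ALPHA_GRID = np.round(np.arange(0.0, 3.0 + 1e-9, 0.05), 10)
DEFAULT_SERIES_PER_ALPHA = 20
DEFAULT_SERIES_LENGTH = 2**14


@dataclass
class TrainingSet:
    """Feature matrix of ordinal probabilities with known alpha labels."""

    features: np.ndarray  # (n_rows, D!)
    labels: np.ndarray  # (n_rows,)
    meta: dict = field(default_factory=dict)


@dataclass
class RegressorModel:
    """Weights and metadata of the fitted two-layer network."""

    W: np.ndarray  # (D!, hidden)
    b: np.ndarray  # (hidden,)
    W_out: np.ndarray  # (hidden,)
    b_out: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    hidden_activation: str
    output_activation: str
    config: OrdinalConfig
    alpha_min: float
    alpha_max: float
    meta: dict = field(default_factory=dict)
    loss_curve: list = field(default_factory=list)
    validation_curve: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return int(self.W.shape[0])


def build_training_set(
    alpha_grid=None,
    series_per_alpha: int = DEFAULT_SERIES_PER_ALPHA,
    series_length: int = DEFAULT_SERIES_LENGTH,
    config: OrdinalConfig | None = None,
    seed: int = 0,
) -> TrainingSet:
    """Ordinal-probability features of seeded flicker-noise series.

    Generates ``series_per_alpha`` independent flicker-noise series for
    every exponent in ``alpha_grid``, computes their ordinal
    distributions, and returns the shuffled feature matrix.  Fully
    reproducible from ``seed``.
    """
    config = config or OrdinalConfig()
    grid = np.asarray(DEFAULT_ALPHA_GRID if alpha_grid is None else alpha_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("alpha grid must be non-empty")
    if series_per_alpha < 1:
        raise ValueError("need at least one series per alpha")
    if series_length < config.min_length():
        raise ValueError(
            f"series_length {series_length} is below the ordinal minimum {config.min_length()}"
        )
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(grid.size * series_per_alpha + 1)
    n_rows = grid.size * series_per_alpha
    X = np.empty((n_rows, config.n_patterns))
    y = np.empty(n_rows)
    row = 0
    for alpha in grid:
        for _ in range(series_per_alpha):
            s = flicker_noise(alpha, series_length, seed=np.random.default_rng(streams[row]))
            X[row] = ordinal_distribution(s, config).probabilities
            y[row] = alpha
            row += 1
    perm = np.random.default_rng(streams[-1]).permutation(n_rows)
    meta = {
        "alpha_grid": grid.tolist(),
        "series_per_alpha": int(series_per_alpha),
        "series_length": int(series_length),
        "seed": int(seed),
        "config": config.to_dict(),
    }
    return TrainingSet(features=X[perm], labels=y[perm], meta=meta)


def train(
    training_set: TrainingSet,
    hidden_units: int = 128,
    epochs: int = 2000,
    l2_penalty: float = 10.0,
    seed: int = 0,
) -> RegressorModel:
    """Fit the network on (ordinal probabilities -> alpha).

    The data are split 90/10 into train/validation by a seeded
    permutation; the network is fitted on the training part by full-batch
    L-BFGS on ridge-penalised mean squared error (``epochs`` caps the
    iteration count) and the held-out validation MSE is recorded in the
    model metadata.  The fairly strong default L2 penalty matters: the
    720 probability features are strongly collinear and the penalty both
    improves alpha recovery on held-out flicker noise and keeps
    predictions stable for inputs off the flicker-noise manifold.
    Deterministic given ``seed``.  Raises on degenerate label sets and on
    divergent (non-finite) fits.
    """
    from sklearn.neural_network import MLPRegressor
    from sklearn.preprocessing import StandardScaler

    X, y = training_set.features, training_set.labels
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 distinct alpha labels")
    n = X.shape[0]
    perm = np.random.default_rng(seed).permutation(n)
    n_val = max(1, n // 10)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    scaler = StandardScaler().fit(X[tr_idx])
    net = MLPRegressor(
        hidden_layer_sizes=(hidden_units,),
        activation="tanh",
        solver="lbfgs",
        alpha=l2_penalty,
        max_iter=epochs,
        random_state=seed,
    )
    net.fit(scaler.transform(X[tr_idx]), y[tr_idx])
    if not all(np.all(np.isfinite(c)) for c in net.coefs_ + net.intercepts_):
        raise RuntimeError("training diverged to non-finite weights")
    train_mse = float(np.mean((net.predict(scaler.transform(X[tr_idx])) - y[tr_idx]) ** 2))
    val_mse = float(np.mean((net.predict(scaler.transform(X[val_idx])) - y[val_idx]) ** 2))
    if not (math.isfinite(train_mse) and math.isfinite(val_mse)):
        raise RuntimeError("training loss diverged (NaN); try fewer iterations or more data")
    meta = dict(training_set.meta)
    meta.update(
        {
            "hidden_units": int(hidden_units),
            "epochs": int(epochs),
            "l2_penalty": float(l2_penalty),
            "train_seed": int(seed),
            "n_iter": int(net.n_iter_),
            "train_mse": train_mse,
            "val_mse": val_mse,
        }
    )
    config = OrdinalConfig.from_dict(training_set.meta["config"]) if "config" in training_set.meta else OrdinalConfig()
    return RegressorModel(
        W=net.coefs_[0],
        b=net.intercepts_[0],
        W_out=net.coefs_[1][:, 0],
        b_out=float(net.intercepts_[1][0]),
        feature_mean=scaler.mean_,
        feature_scale=scaler.scale_,
        hidden_activation="tanh",
        output_activation="identity",
        config=config,
        alpha_min=float(y.min()),
        alpha_max=float(y.max()),
        meta=meta,
        loss_curve=[train_mse],
        validation_curve=[val_mse],
    )


def _forward(model: RegressorModel, p: np.ndarray) -> float:
    z = (p - model.feature_mean) / model.feature_scale
    h = np.tanh(z @ model.W + model.b)
    return float(h @ model.W_out + model.b_out)


def predict(model: RegressorModel, dist: OrdinalDistribution, clip: bool = True) -> float:
    """Effective flicker exponent ``alpha_e`` for one ordinal distribution.

    By default the output is clipped to the training label range — a
    dense network extrapolated outside its label hull is meaningless.
    """
    if dist.config != model.config:
        raise ValueError(
            f"ordinal config mismatch: model was trained with {model.config}, got {dist.config}"
        )
    alpha_e = _forward(model, dist.probabilities)
    if not math.isfinite(alpha_e):
        raise RuntimeError("prediction is non-finite")
    if clip:
        alpha_e = min(max(alpha_e, model.alpha_min), model.alpha_max)
    return alpha_e


def save_model(model: RegressorModel, path) -> None:
    """Serialise the model to a single JSON file (bit-exact round trip)."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "config": model.config.to_dict(),
        "hidden_activation": model.hidden_activation,
        "output_activation": model.output_activation,
        "alpha_min": model.alpha_min,
        "alpha_max": model.alpha_max,
        "W": model.W.tolist(),
        "b": model.b.tolist(),
        "W_out": model.W_out.tolist(),
        "b_out": model.b_out,
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "meta": model.meta,
        "loss_curve": model.loss_curve,
        "validation_curve": model.validation_curve,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> RegressorModel:
    """Load a model saved by :func:`save_model`, validating its shape."""
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format version {version!r}")
    try:
        config = OrdinalConfig.from_dict(payload["config"])
        model = RegressorModel(
            W=np.asarray(payload["W"], dtype=float),
            b=np.asarray(payload["b"], dtype=float),
            W_out=np.asarray(payload["W_out"], dtype=float),
            b_out=float(payload["b_out"]),
            feature_mean=np.asarray(payload["feature_mean"], dtype=float),
            feature_scale=np.asarray(payload["feature_scale"], dtype=float),
            hidden_activation=payload["hidden_activation"],
            output_activation=payload["output_activation"],
            config=config,
            alpha_min=float(payload["alpha_min"]),
            alpha_max=float(payload["alpha_max"]),
            meta=payload.get("meta", {}),
            loss_curve=payload.get("loss_curve", []),
            validation_curve=payload.get("validation_curve", []),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: corrupt model file ({exc})") from exc
    if model.W.ndim != 2 or model.W.shape[0] != config.n_patterns:
        raise ValueError(
            f"{path}: weight shape {model.W.shape} inconsistent with D={config.D} "
            f"({config.n_patterns} features)"
        )
    return model
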