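"""Single-input, multi-output feedforward network for regional amyloid forecasting.

The model maps one CSF analyte value to the 37 regional PET SUVR values
simultaneously.  Architecture: input -> three ReLU hidden layers -> linear
output, trained by mini-batch ADAM on mean squared error for a fixed number
of epochs (no early stopping), with inverted dropout after each hidden
activation during training only.  Training a multi-output network lets the
model exploit the covariance structure of the regional outputs, which is what
makes a single scalar input sufficient.

Everything is plain numpy; inference is a deterministic forward pass.  The
analyte is z-scored with training-set statistics stored on the model, so
analytes on very different scales (occupancy percentages ~20 vs ratios ~0.05)
train equally well.  Outputs stay in raw SUVR.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .scale import mean_cortical_suvr

__all__ = [
    "NetworkConfig",
    "MLPNetwork",
    "TrainedForecaster",
    "EnsemblePrediction",
    "ForecastEnsemble",
    "build_network",
    "train",
    "predict",
    "grid_search",
    "bootstrap_ensemble",
    "save_forecaster",
    "load_forecaster",
    "save_training_log",
]

_ADAM_BETA1 = 0.9
_ADAM_BETA2 = 0.999
_ADAM_EPS = 1e-8


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the forecaster.

    Exactly three hidden layers; training always runs ``epochs`` epochs
    (default 100) with no early stopping.
    """

    hidden_widths: tuple[int, int, int] = (64, 64, 32)
    dropout_rate: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.hidden_widths) != 3:
            raise ValueError("hidden_widths must name exactly 3 hidden layers")
        if any(int(w) < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive integers")
        object.__setattr__(self, "hidden_widths", tuple(int(w) for w in self.hidden_widths))
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


DEFAULT_GRID: tuple[NetworkConfig, ...] = tuple(
    NetworkConfig(hidden_widths=w, dropout_rate=d, learning_rate=lr)
    for w in ((32, 32, 16), (64, 64, 32), (128, 64, 32))
    for d in (0.1, 0.3)
    for lr in (1e-3, 1e-2)
)


class MLPNetwork:
    """Weights and forward/backward passes of the 4-layer perceptron."""

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray],
                 config: NetworkConfig):
        self.weights = weights
        self.biases = biases
        self.config = config

    @property
    def n_outputs(self) -> int:
        return self.weights[-1].shape[1]

    def param_count(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def forward(self, z: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Forward pass on standardized input ``z`` of shape (n, 1).

        With ``dropout_rng`` set, inverted dropout is applied after each hidden
        activation (training mode); returns ``(output, cache)`` where the cache
        holds activations and dropout masks for backprop.  Without it, the pass
        is deterministic and only the output is returned.
        """
        p = self.config.dropout_rate
        a = np.asarray(z, dtype=float)
        activations = [a]
        pre_acts = []
        masks = []
        n_layers = len(self.weights)
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            pre = a @ w + b
            pre_acts.append(pre)
            if li < n_layers - 1:
                a = np.maximum(pre, 0.0)
                if dropout_rng is not None and p > 0:
                    mask = (dropout_rng.random(a.shape) >= p) / (1.0 - p)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                activations.append(a)
            else:
                a = pre  # linear output
        if dropout_rng is None:
            return a
        return a, (activations, pre_acts, masks)

    def backward(self, cache, d_out: np.ndarray):
        """Gradients of the loss wrt every weight and bias, given d(loss)/d(output)."""
        activations, pre_acts, masks = cache
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = d_out
        for li in range(len(self.weights) - 1, -1, -1):
            grads_w[li] = activations[li].T @ delta if li < len(activations) else None
            grads_b[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.weights[li].T
                delta = delta * (pre_acts[li - 1] > 0)
                if masks[li - 1] is not None:
                    delta = delta * masks[li - 1]
        return grads_w, grads_b


def build_network(config: NetworkConfig, n_outputs: int) -> MLPNetwork:
    """Initialize the 1 -> h1 -> h2 -> h3 -> n_outputs network.

    He-scaled normal initialization (suits ReLU) from ``config.seed``; biases
    start at zero.
    """
    if n_outputs < 1:
        raise ValueError(f"n_outputs must be >= 1, got {n_outputs}")
    rng = np.random.default_rng(config.seed)
    sizes = [1, *config.hidden_widths, n_outputs]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPNetwork(weights, biases, config)


@dataclass
class TrainedForecaster:
    """A trained network plus everything needed for deterministic inference."""

    network: MLPNetwork
    config: NetworkConfig
    input_analyte: str
    output_region_names: list[str]
    x_mean: float
    x_sd: float
    x_min: float
    x_max: float
    training_loss_history: list[float]
    split_meta: dict = field(default_factory=dict)

    def predict(self, x, warn_extrapolation: bool = True) -> np.ndarray:
        """Regional SUVR predictions, shape (n, n_regions); dropout disabled."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ValueError("analyte values must be finite")
        if warn_extrapolation and (x.min() < self.x_min or x.max() > self.x_max):
            warnings.warn(
                f"analyte values outside training range "
                f"[{self.x_min:.4g}, {self.x_max:.4g}]; predictions are extrapolations",
                stacklevel=2,
            )
        z = (x - self.x_mean) / self.x_sd
        return self.network.forward(z.reshape(-1, 1))

    def predict_mean_cortical(self, x, atlas) -> np.ndarray:
        """Mean cortical SUVR derived from the regional predictions."""
        pred = self.predict(x)
        return np.array([mean_cortical_suvr(row, atlas) for row in pred])


def _validate_xy(x, Y):
    x = np.asarray(x, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    if x.shape[0] != Y.shape[0]:
        raise ValueError(f"x has {x.shape[0]} rows but Y has {Y.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(Y))):
        raise ValueError("training data must be finite (no missing values)")
    return x, Y


def train(
    network: MLPNetwork,
    x,
    Y,
    config: NetworkConfig | None = None,
    input_analyte: str = "analyte",
    output_region_names: Sequence[str] | None = None,
    split_meta: dict | None = None,
) -> TrainedForecaster:
    """Run exactly ``config.epochs`` epochs of mini-batch ADAM on MSE.

    Dropout is active only during the training passes; the per-epoch loss
    history is the full-training-set MSE with dropout off.  Deterministic
    given ``config.seed``.
    """
    config = config or network.config
    x, Y = _validate_xy(x, Y)
    if Y.shape[1] != network.n_outputs:
        raise ValueError(f"network has {network.n_outputs} outputs but Y has {Y.shape[1]} columns")
    x_mean = float(x.mean())
    x_sd = float(x.std())
    if x_sd == 0:
        x_sd = 1.0
    z = ((x - x_mean) / x_sd).reshape(-1, 1)

    rng = np.random.default_rng(config.seed)
    m_w = [np.zeros_like(w) for w in network.weights]
    v_w = [np.zeros_like(w) for w in network.weights]
    m_b = [np.zeros_like(b) for b in network.biases]
    v_b = [np.zeros_like(b) for b in network.biases]
    t = 0
    n = z.shape[0]
    loss_history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            zb, yb = z[idx], Y[idx]
            out, cache = network.forward(zb, dropout_rng=rng)
            d_out = 2.0 * (out - yb) / out.size
            grads_w, grads_b = network.backward(cache, d_out)
            t += 1
            bias_c1 = 1.0 - _ADAM_BETA1 ** t
            bias_c2 = 1.0 - _ADAM_BETA2 ** t
            for li in range(len(network.weights)):
                for params, grads, m, v in (
                    (network.weights, grads_w, m_w, v_w),
                    (network.biases, grads_b, m_b, v_b),
                ):
                    g = grads[li]
                    m[li] = _ADAM_BETA1 * m[li] + (1 - _ADAM_BETA1) * g
                    v[li] = _ADAM_BETA2 * v[li] + (1 - _ADAM_BETA2) * g * g
                    params[li] -= config.learning_rate * (m[li] / bias_c1) / (
                        np.sqrt(v[li] / bias_c2) + _ADAM_EPS
                    )
        pred = network.forward(z)
        loss_history.append(float(np.mean((pred - Y) ** 2)))

    names = (list(output_region_names) if output_region_names is not None
             else [f"region_{j}" for j in range(network.n_outputs)])
    return TrainedForecaster(
        network=network,
        config=config,
        input_analyte=input_analyte,
        output_region_names=names,
        x_mean=x_mean,
        x_sd=x_sd,
        x_min=float(x.min()),
        x_max=float(x.max()),
        training_loss_history=loss_history,
        split_meta=dict(split_meta or {}),
    )


def predict(model: TrainedForecaster, x, **kwargs) -> np.ndarray:
    """Module-level alias for :meth:`TrainedForecaster.predict`."""
    return model.predict(x, **kwargs)


def grid_search(
    x,
    Y,
    grid: Sequence[NetworkConfig] = DEFAULT_GRID,
    validation_fraction: float = 0.2,
    seed: int | None = None,
) -> tuple[NetworkConfig, list[dict]]:
    """Coarse grid search on an inner split of the training data.

    Each config is trained once on the inner-train part and scored by
    validation MSE; ties break toward fewer parameters, then lower dropout.
    Returns the winning config (with its seed set from ``seed``) and the
    per-config score records.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    x, Y = _validate_xy(x, Y)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    n_val = max(1, int(round(validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    scores: list[dict] = []
    for ci, cfg in enumerate(grid):
        cfg_seeded = replace(cfg, seed=(0 if seed is None else seed) * 1000 + ci)
        net = build_network(cfg_seeded, Y.shape[1])
        model = train(net, x[tr_idx], Y[tr_idx], cfg_seeded)
        val_mse = float(np.mean((model.predict(x[val_idx], warn_extrapolation=False) - Y[val_idx]) ** 2))
        scores.append({"config": cfg, "val_mse": val_mse,
                       "n_params": net.param_count()})
    best = min(
        range(len(grid)),
        key=lambda i: (scores[i]["val_mse"], scores[i]["n_params"], grid[i].dropout_rate),
    )
    best_cfg = replace(grid[best], seed=seed)
    return best_cfg, scores


@dataclass
class EnsemblePrediction:
    """Stacked per-member regional predictions, shape (members, n, regions)."""

    member_predictions: np.ndarray
    resample_seeds: list[int]

    @property
    def n_members(self) -> int:
        return self.member_predictions.shape[0]

    def mean(self) -> np.ndarray:
        return self.member_predictions.mean(axis=0)

    def percentile_ci(self, level: float = 95.0) -> tuple[np.ndarray, np.ndarray]:
        lo = (100.0 - level) / 2.0
        return (np.percentile(self.member_predictions, lo, axis=0),
                np.percentile(self.member_predictions, 100.0 - lo, axis=0))


@dataclass
class ForecastEnsemble:
    """Bootstrap ensemble of forecasters for CI construction."""

    members: list[TrainedForecaster]
    resample_seeds: list[int]

    def predict(self, x) -> EnsemblePrediction:
        preds = np.stack([m.predict(x, warn_extrapolation=False) for m in self.members])
        return EnsemblePrediction(preds, self.resample_seeds)


def bootstrap_ensemble(
    x_train,
    Y_train,
    config: NetworkConfig,
    n_members: int = 100,
    seed: int | None = None,
    grid: Sequence[NetworkConfig] | None = None,
) -> ForecastEnsemble:
    """Train ``n_members`` forecasters on bootstrap resamples of the training set.

    Each member resamples (with replacement) ``round(0.8 * n_train)``
    participants — 80% of the training set, 64% of a full cohort split 80/20 —
    and, when a reduced ``grid`` is supplied, re-tunes over it on the resample
    before the final fit.
    """
    if n_members < 2:
        raise ValueError("n_members must be >= 2")
    x, Y = _validate_xy(x_train, Y_train)
    n = x.shape[0]
    size = int(round(0.8 * n))
    root = np.random.SeedSequence(seed)
    members: list[TrainedForecaster] = []
    seeds: list[int] = []
    for k, child in enumerate(root.spawn(n_members)):
        rng = np.random.default_rng(child)
        member_seed = int(rng.integers(0, 2**31 - 1))
        seeds.append(member_seed)
        idx = rng.integers(0, n, size=size)
        cfg = config
        if grid:
            cfg, _ = grid_search(x[idx], Y[idx], grid, seed=member_seed)
        cfg = replace(cfg, seed=member_seed)
        net = build_network(cfg, Y.shape[1])
        members.append(train(net, x[idx], Y[idx], cfg,
                             split_meta={"resample_size": size, "member": k}))
    return ForecastEnsemble(members, seeds)


def save_training_log(model: TrainedForecaster, path) -> None:
    """Write the per-epoch training MSE to a two-column CSV (epoch, mse)."""
    lines = ["epoch,mse"]
    lines += [f"{i + 1},{v!r}" for i, v in enumerate(model.training_loss_history)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# serialization: JSON manifest with full-precision weight arrays

def save_forecaster(model: TrainedForecaster, path) -> None:
    doc = {
        "config": {
            "hidden_widths": list(model.config.hidden_widths),
            "dropout_rate": model.config.dropout_rate,
            "learning_rate": model.config.learning_rate,
            "epochs": model.config.epochs,
            "batch_size": model.config.batch_size,
            "seed": model.config.seed,
        },
        "input_analyte": model.input_analyte,
        "output_region_names": model.output_region_names,
        "x_mean": model.x_mean,
        "x_sd": model.x_sd,
        "x_min": model.x_min,
        "x_max": model.x_max,
        "training_loss_history": model.training_loss_history,
        "split_meta": model.split_meta,
        "weights": [w.tolist() for w in model.network.weights],
        "biases": [b.tolist() for b in model.network.biases],
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_forecaster(path) -> TrainedForecaster:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    cfg = NetworkConfig(
        hidden_widths=tuple(doc["config"]["hidden_widths"]),
        dropout_rate=doc["config"]["dropout_rate"],
        learning_rate=doc["config"]["learning_rate"],
        epochs=doc["config"]["epochs"],
        batch_size=doc["config"]["batch_size"],
        seed=doc["config"]["seed"],
    )
    net = MLPNetwork([np.array(w) for w in doc["weights"]],
                     [np.array(b) for b in doc["biases"]], cfg)
    return TrainedForecaster(
        network=net,
        config=cfg,
        input_analyte=doc["input_analyte"],
        output_region_names=doc["output_region_names"],
        x_mean=doc["x_mean"],
        x_sd=doc["x_sd"],
        x_min=doc["x_min"],
        x_max=doc["x_max"],
        training_loss_history=doc["training_loss_history"],
        split_meta=doc["split_meta"],
    )
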