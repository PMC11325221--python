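"""QSPR modelling of enzyme-inactivation rate constants from mixture
descriptors with single-hidden-layer MLPs.

The modelling assumption is that the inactivation rate constant of an
enzyme in a DES is a smooth function of the solvent's mixture
descriptors, k = f(S¹_mix, …, S¹⁰_mix).  The workflow is

1. input selection by Spearman rank correlation between each descriptor
   and k (|ρ| above a configurable cutoff);
2. a random split into a calibration set and a fully held-out
   prediction set, with the calibration set divided 70/15/15 into
   training / test (early-stopping) / validation blocks;
3. a randomized architecture search over hidden-layer widths 4–13 and
   activation pairs drawn from {identity, logistic, tanh, exponential},
   each candidate trained by full-batch gradient-descent
   backpropagation on a sum-of-squares error with early stopping on the
   test block; candidates are ranked by validation-block R².

Rate constants span roughly five decades (2·10⁻⁴…51 h⁻¹), which makes a
raw sum-of-squares fit degenerate — the response is therefore modelled
as log₁₀(k) by default, with the inverse transform applied on output.
Inputs are z-scored on the training block (the exponential activation
saturates instantly otherwise), and the response is z-scored internally
for training with the inverse applied in :func:`predict`.

All randomness (splits, architecture sampling, weight init) flows from
explicit seeds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .sigma_profiles import N_REGIONS

__all__ = [
    "ACTIVATIONS",
    "QSPRDataset",
    "SplitSpec",
    "Partition",
    "MLPArchitecture",
    "TrainingSettings",
    "TrainedModel",
    "spearman_matrix",
    "select_inputs",
    "split_dataset",
    "train_mlp",
    "random_search",
    "predict",
    "save_model",
    "load_model",
]

ACTIVATIONS = ("identity", "logistic", "tanh", "exponential")

#: Pre-activation clip for the exponential activation, preventing overflow.
EXP_CLIP = 30.0

DESCRIPTOR_COLUMNS = tuple(f"S{i + 1}" for i in range(N_REGIONS))


# ---------------------------------------------------------------------------
# data containers

@dataclass
class QSPRDataset:
    """Rows of mixture descriptors with a rate-constant response.

    ``table`` has columns ``label``, ``S1``…``S10`` and ``k_per_h``;
    ``transform`` ({none|log10|scaled}) sets the response scale used for
    training.  ``scaled`` is min–max to [0, 1] with the bounds taken
    from the data at construction.
    """

    table: pd.DataFrame
    enzyme: str = ""
    transform: str = "log10"
    scale_bounds: tuple | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ("k_per_h", *DESCRIPTOR_COLUMNS) if c not in self.table]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        X = self.table[list(DESCRIPTOR_COLUMNS)].to_numpy(float)
        k = self.table["k_per_h"].to_numpy(float)
        if not np.all(np.isfinite(X)):
            raise ValueError("descriptor values must be finite (no missing values)")
        if not np.all(np.isfinite(k)):
            raise ValueError("responses must be finite")
        if self.transform not in ("none", "log10", "scaled"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "log10" and np.any(k <= 0):
            raise ValueError("log10 transform requires strictly positive k")
        if self.transform == "scaled" and self.scale_bounds is None:
            self.scale_bounds = (float(k.min()), float(k.max()))

    @property
    def n(self) -> int:
        return len(self.table)

    def descriptors(self) -> np.ndarray:
        return self.table[list(DESCRIPTOR_COLUMNS)].to_numpy(float)

    def response(self) -> np.ndarray:
        """The response on the training scale (transform applied)."""
        k = self.table["k_per_h"].to_numpy(float)
        if self.transform == "log10":
            return np.log10(k)
        if self.transform == "scaled":
            lo, hi = self.scale_bounds
            return (k - lo) / (hi - lo) if hi > lo else np.zeros_like(k)
        return k

    def inverse_transform(self, y: np.ndarray) -> np.ndarray:
        if self.transform == "log10":
            return 10.0**y
        if self.transform == "scaled":
            lo, hi = self.scale_bounds
            return y * (hi - lo) + lo
        return y


@dataclass(frozen=True)
class SplitSpec:
    """Calibration/prediction split plus the 70/15/15 calibration blocks."""

    calibration_fraction: float = 55.0 / 84.0
    train_fraction: float = 0.70
    test_fraction: float = 0.15
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.test_fraction, self.validation_fraction)
        if any(f <= 0 for f in fracs) or not (0 < self.calibration_fraction <= 1):
            raise ValueError("fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-12:
            raise ValueError("train/test/validation fractions must sum to 1")


@dataclass(frozen=True)
class Partition:
    """Disjoint, exhaustive index blocks of a dataset."""

    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray
    prediction: np.ndarray

    @property
    def calibration(self) -> np.ndarray:
        return np.concatenate([self.train, self.test, self.validation])


@dataclass(frozen=True)
class MLPArchitecture:
    """Single-hidden-layer perceptron shape and activation pair."""

    n_inputs: int
    n_hidden: int
    hidden_activation: str = "tanh"
    output_activation: str = "identity"

    def __post_init__(self) -> None:
        if not 4 <= self.n_hidden <= 13:
            raise ValueError("hidden width must lie in [4, 13]")
        if self.hidden_activation not in ACTIVATIONS:
            raise ValueError(f"unknown hidden activation {self.hidden_activation!r}")
        if self.output_activation not in ACTIVATIONS:
            raise ValueError(f"unknown output activation {self.output_activation!r}")
        if self.n_inputs < 1:
            raise ValueError("need at least one input")

    @property
    def name(self) -> str:
        """Field-standard name, e.g. ``MLP 8-6-1``."""
        return f"MLP {self.n_inputs}-{self.n_hidden}-1"


@dataclass(frozen=True)
class TrainingSettings:
    """Backpropagation hyper-parameters (documented defaults, not claims)."""

    learning_rate: float = 0.05
    max_epochs: int = 4000
    patience: int = 300
    max_restarts: int = 5
    seed: int = 0


@dataclass
class TrainedModel:
    """A trained MLP with its standardization constants and metrics."""

    architecture: MLPArchitecture
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    transform: str
    scale_bounds: tuple | None
    input_indices: tuple
    history: list
    metrics: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        h, d = self.architecture.n_hidden, self.architecture.n_inputs
        if self.W1.shape != (d, h) or self.W2.shape != (h, 1):
            raise ValueError("weight shapes inconsistent with architecture")
        if not self.history:
            raise ValueError("training history must be non-empty")


# ---------------------------------------------------------------------------
# input selection

def spearman_matrix(dataset: QSPRDataset) -> np.ndarray:
    """Spearman ρ between each of the ten descriptors and the response.

    Ties get average ranks (scipy's convention).  A constant descriptor
    column has undefined ρ; it is reported as 0 with a warning.
    """
    if dataset.n < 3:
        raise ValueError("need at least 3 rows for rank correlations")
    X = dataset.descriptors()
    y = dataset.response()
    rho = np.zeros(N_REGIONS)
    for i in range(N_REGIONS):
        col = X[:, i]
        if np.ptp(col) == 0 or np.ptp(y) == 0:
            warnings.warn(f"S{i + 1}: constant column, Spearman rho undefined; "
                          "reported as 0", stacklevel=2)
            rho[i] = 0.0
        else:
            rho[i] = spearmanr(col, y).statistic
    return rho


def select_inputs(correlations: np.ndarray, threshold: float = 0.4) -> tuple[int, ...]:
    """Descriptor indices (0-based) with |ρ| ≥ threshold, in descriptor order."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    idx = tuple(int(i) for i in np.flatnonzero(np.abs(correlations) >= threshold))
    if not idx:
        raise ValueError(
            f"no descriptor reaches |rho| >= {threshold}; lower the threshold"
        )
    return idx


# ---------------------------------------------------------------------------
# splitting

def split_dataset(n: int, spec: SplitSpec) -> Partition:
    """Seed-reproducible random partition of ``range(n)``.

    The calibration count is ``floor(calibration_fraction·n)``; its
    complement is the prediction set.  Within calibration, test and
    validation counts are floored and the remainder goes to training.
    """
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_cal = int(math.floor(spec.calibration_fraction * n))
    n_test = int(math.floor(spec.test_fraction * n_cal))
    n_val = int(math.floor(spec.validation_fraction * n_cal))
    n_train = n_cal - n_test - n_val
    if min(n_train, n_test, n_val, n - n_cal) < 1:
        raise ValueError(f"empty block in split of n={n}: "
                         f"train={n_train}, test={n_test}, val={n_val}, "
                         f"pred={n - n_cal}")
    train = np.sort(perm[:n_train])
    test = np.sort(perm[n_train:n_train + n_test])
    val = np.sort(perm[n_train + n_test:n_cal])
    pred = np.sort(perm[n_cal:])
    return Partition(train=train, test=test, validation=val, prediction=pred)


# ---------------------------------------------------------------------------
# the network

def _activate(name: str, z: np.ndarray) -> np.ndarray:
    if name == "identity":
        return z
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -EXP_CLIP, EXP_CLIP)))
    if name == "tanh":
        return np.tanh(z)
    if name == "exponential":
        return np.exp(np.clip(z, -EXP_CLIP, EXP_CLIP))
    raise ValueError(name)


def _activate_deriv(name: str, a: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation value a
    if name == "identity":
        return np.ones_like(a)
    if name == "logistic":
        return a * (1.0 - a)
    if name == "tanh":
        return 1.0 - a**2
    if name == "exponential":
        return a
    raise ValueError(name)


def _init_weights(arch: MLPArchitecture, rng: np.random.Generator):
    d, h = arch.n_inputs, arch.n_hidden
    W1 = rng.uniform(-1, 1, (d, h)) / math.sqrt(d)
    b1 = np.zeros(h)
    W2 = rng.uniform(-1, 1, (h, 1)) / math.sqrt(h)
    b2 = np.zeros(1)
    return W1, b1, W2, b2


def _forward(arch, W1, b1, W2, b2, X):
    Z1 = X @ W1 + b1
    A1 = _activate(arch.hidden_activation, Z1)
    Z2 = A1 @ W2 + b2
    A2 = _activate(arch.output_activation, Z2)
    return A1, A2[:, 0]


def train_mlp(
    dataset: QSPRDataset,
    partition: Partition,
    architecture: MLPArchitecture,
    input_indices: tuple[int, ...] | None = None,
    settings: TrainingSettings = TrainingSettings(),
) -> TrainedModel:
    """Train one MLP by full-batch gradient-descent backpropagation.

    The loss is the sum of squared errors on the (standardized) training
    block; the per-epoch history records it.  Early stopping monitors
    the test block: training halts when the test error has not improved
    for ``patience`` epochs and the best-test-error weights are kept.
    The validation block is never touched during training; its R² is
    computed once, for reporting and model selection.  On divergence
    (non-finite loss) training restarts with half the step size, up to
    ``max_restarts`` times.
    """
    if input_indices is None:
        input_indices = tuple(range(N_REGIONS))
    input_indices = tuple(int(i) for i in input_indices)
    if len(input_indices) != architecture.n_inputs:
        raise ValueError("architecture n_inputs must match the selected inputs")

    X_all = dataset.descriptors()[:, input_indices]
    y_all = dataset.response()

    tr, te, va = partition.train, partition.test, partition.validation
    x_mean = X_all[tr].mean(axis=0)
    x_std = X_all[tr].std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_mean = float(y_all[tr].mean())
    y_std = float(y_all[tr].std()) or 1.0

    Xs = (X_all - x_mean) / x_std
    ys = (y_all - y_mean) / y_std
    Xtr, ytr = Xs[tr], ys[tr]
    Xte, yte = Xs[te], ys[te]

    n_tr = len(tr)
    lr = settings.learning_rate
    last_error: Exception | None = None
    for attempt in range(settings.max_restarts + 1):
        rng = np.random.default_rng(settings.seed + 1009 * attempt)
        W1, b1, W2, b2 = _init_weights(architecture, rng)
        _, yhat0 = _forward(architecture, W1, b1, W2, b2, Xtr)
        _, yhat_te0 = _forward(architecture, W1, b1, W2, b2, Xte)
        best = (float(np.sum((yhat_te0 - yte) ** 2)),
                W1.copy(), b1.copy(), W2.copy(), b2.copy(), -1)
        history: list[float] = [float(np.sum((yhat0 - ytr) ** 2))]
        diverged = not math.isfinite(history[0])
        step = lr / (2**attempt)
        since_best = 0
        for epoch in range(settings.max_epochs):
            if diverged:
                break
            with np.errstate(over="ignore", invalid="ignore"):
                A1, yhat = _forward(architecture, W1, b1, W2, b2, Xtr)
                err = yhat - ytr
                sse = float(err @ err)
            if not math.isfinite(sse):
                diverged = True
                break
            if epoch > 0:
                history.append(sse)
            # backprop of the mean-squared error (same minimizer as SSE)
            d2 = (2.0 / n_tr) * err * _activate_deriv(
                architecture.output_activation, yhat
            )
            gW2 = A1.T @ d2[:, None]
            gb2 = np.array([d2.sum()])
            d1 = (d2[:, None] @ W2.T) * _activate_deriv(
                architecture.hidden_activation, A1
            )
            gW1 = Xtr.T @ d1
            gb1 = d1.sum(axis=0)
            W1 -= step * gW1
            b1 -= step * gb1
            W2 -= step * gW2
            b2 -= step * gb2
            with np.errstate(over="ignore", invalid="ignore"):
                _, yhat_te = _forward(architecture, W1, b1, W2, b2, Xte)
                sse_te = float(np.sum((yhat_te - yte) ** 2))
            if not math.isfinite(sse_te):
                diverged = True
                break
            if sse_te < best[0] - 1e-12:
                best = (sse_te, W1.copy(), b1.copy(), W2.copy(), b2.copy(), epoch)
                since_best = 0
            else:
                since_best += 1
                if since_best >= settings.patience:
                    break
        if not diverged:
            break
        last_error = RuntimeError(
            f"{architecture.name}: training diverged (attempt {attempt + 1})"
        )
    else:
        raise last_error

    _, W1, b1, W2, b2, best_epoch = best
    model = TrainedModel(
        architecture=architecture,
        W1=W1, b1=b1, W2=W2, b2=b2,
        x_mean=x_mean, x_std=x_std,
        y_mean=y_mean, y_std=y_std,
        transform=dataset.transform,
        scale_bounds=dataset.scale_bounds,
        input_indices=input_indices,
        history=history if history else [math.inf],
        seed=settings.seed,
    )
    model.metrics = _block_metrics(model, dataset, partition)
    return model


def _predict_standardized(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    Xs = (X - model.x_mean) / model.x_std
    _, yhat = _forward(model.architecture, model.W1, model.b1,
                       model.W2, model.b2, Xs)
    return yhat


def _predict_transformed(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Prediction on the (possibly log) training response scale."""
    return _predict_standardized(model, X) * model.y_std + model.y_mean


def _block_metrics(model, dataset, partition) -> dict:
    X_all = dataset.descriptors()[:, model.input_indices]
    y_all = dataset.response()
    out = {}
    for name, idx in (("train", partition.train), ("test", partition.test),
                      ("validation", partition.validation)):
        yhat = _predict_transformed(model, X_all[idx])
        y = y_all[idx]
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(np.sum((y - yhat) ** 2))
        out[f"r2_{name}"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
        out[f"rmse_{name}"] = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return out


def predict(model: TrainedModel, descriptors: np.ndarray) -> np.ndarray:
    """Predict k (original units, h⁻¹) for rows of selected descriptors.

    ``descriptors`` may be the full 10-column matrix (the model's input
    columns are selected) or already restricted to the model's inputs.
    A single vector is accepted and returns a scalar array of shape (1,).
    """
    X = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if X.shape[1] == N_REGIONS and model.architecture.n_inputs != N_REGIONS:
        X = X[:, model.input_indices]
    if X.shape[1] != model.architecture.n_inputs:
        raise ValueError(
            f"expected {model.architecture.n_inputs} descriptor columns, "
            f"got {X.shape[1]}"
        )
    y = _predict_transformed(model, X)
    if model.transform == "log10":
        return 10.0**y
    if model.transform == "scaled":
        lo, hi = model.scale_bounds
        return y * (hi - lo) + lo
    return y


def random_search(
    dataset: QSPRDataset,
    partition: Partition,
    input_indices: tuple[int, ...],
    n_candidates: int = 20,
    seed: int = 0,
    settings: TrainingSettings | None = None,
    architectures: list[MLPArchitecture] | None = None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Randomized architecture search, ranked by validation R².

    Hidden widths are drawn uniformly from 4–13; the activation pair
    cycles through a seeded shuffle of all 16 hidden/output combinations
    (reshuffled each cycle), so any budget of at least 16 candidates
    covers every pair — iid pair sampling routinely leaves the few
    viable combinations undrawn even in large budgets.  ``architectures``
    restricts the pool to an explicit list instead.  Every candidate is
    trained with a seed derived from ``seed``; the winner and a full
    leaderboard (one row per candidate) are returned.
    """
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    rng = np.random.default_rng(seed)
    pairs = [(h, o) for h in ACTIVATIONS for o in ACTIVATIONS]
    pair_order: list[int] = []
    rows = []
    best_model: TrainedModel | None = None
    for c in range(n_candidates):
        if architectures is not None:
            arch = architectures[int(rng.integers(len(architectures)))]
        else:
            if not pair_order:
                pair_order = list(rng.permutation(len(pairs)))
            hidden_act, output_act = pairs[pair_order.pop(0)]
            arch = MLPArchitecture(
                n_inputs=len(input_indices),
                n_hidden=int(rng.integers(4, 14)),
                hidden_activation=hidden_act,
                output_activation=output_act,
            )
        train_settings = replace(
            settings or TrainingSettings(), seed=int(rng.integers(2**31 - 1))
        )
        try:
            model = train_mlp(dataset, partition, arch, input_indices,
                              train_settings)
        except RuntimeError:
            rows.append({"candidate": c, "network": arch.name,
                         "hidden_activation": arch.hidden_activation,
                         "output_activation": arch.output_activation,
                         "r2_validation": -math.inf, "diverged": True})
            continue
        r2v = model.metrics["r2_validation"]
        rows.append({"candidate": c, "network": arch.name,
                     "hidden_activation": arch.hidden_activation,
                     "output_activation": arch.output_activation,
                     "r2_validation": r2v, "diverged": False,
                     **{k: v for k, v in model.metrics.items()
                        if k != "r2_validation"}})
        if best_model is None or (
            math.isfinite(r2v)
            and r2v > best_model.metrics["r2_validation"]
        ):
            best_model = model
    leaderboard = pd.DataFrame(rows).sort_values(
        "r2_validation", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    if best_model is None:
        raise RuntimeError(
            f"all {n_candidates} candidates diverged; leaderboard:\n{leaderboard}"
        )
    return best_model, leaderboard


# ---------------------------------------------------------------------------
# model persistence

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model (architecture, weights, scalers) to JSON."""
    arch = model.architecture
    payload = {
        "architecture": {
            "n_inputs": arch.n_inputs,
            "n_hidden": arch.n_hidden,
            "hidden_activation": arch.hidden_activation,
            "output_activation": arch.output_activation,
        },
        "W1": model.W1.tolist(), "b1": model.b1.tolist(),
        "W2": model.W2.tolist(), "b2": model.b2.tolist(),
        "x_mean": model.x_mean.tolist(), "x_std": model.x_std.tolist(),
        "y_mean": model.y_mean, "y_std": model.y_std,
        "transform": model.transform,
        "scale_bounds": list(model.scale_bounds) if model.scale_bounds else None,
        "input_indices": list(model.input_indices),
        "history": model.history,
        "metrics": model.metrics,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    arch = MLPArchitecture(**payload["architecture"])
    return TrainedModel(
        architecture=arch,
        W1=np.array(payload["W1"]), b1=np.array(payload["b1"]),
        W2=np.array(payload["W2"]), b2=np.array(payload["b2"]),
        x_mean=np.array(payload["x_mean"]), x_std=np.array(payload["x_std"]),
        y_mean=payload["y_mean"], y_std=payload["y_std"],
        transform=payload["transform"],
        scale_bounds=tuple(payload["scale_bounds"]) if payload["scale_bounds"] else None,
        input_indices=tuple(payload["input_indices"]),
        history=payload["history"],
        metrics=payload["metrics"],
        seed=payload["seed"],
    )
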