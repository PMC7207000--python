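"""Two-hidden-layer feed-forward networks for methylation-based traits.

A deliberately small, fully deterministic implementation: exactly two
fully connected hidden layers with tanh, rectifier or maxout
activations, a softmax output for classification or a single linear
neuron for regression, L1/L2 weight penalties, inverted dropout on the
input and hidden layers, and single-threaded minibatch stochastic
gradient descent with Nesterov momentum and polynomial learning-rate
annealing.  Inputs are standardized per feature (mean/sd fitted on the
training portion only and stored with the model).

Model selection follows the study protocol: exhaustive grid search over
declared hyperparameter combinations, scored by sevenfold
cross-validation (log loss for classification, MSE for regression).

Shapes
------
``W1``: (n_inputs, h1) or (n_inputs, h1, channels) for maxout;
``W2``: (h1, h2) likewise; ``W3``: (h2, n_out).  Biases match the
trailing hidden/output dimensions.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

ACTIVATIONS = ("tanh", "rectifier", "maxout")

#: probability floor used before taking logs in the cross-entropy
P_FLOOR = 1e-15


class SpecError(ValueError):
    """Raised on an invalid network specification."""


class DivergenceError(RuntimeError):
    """Raised when training loss becomes non-finite."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training hyperparameters of one network.

    ``hidden_sizes`` must name exactly two hidden layers.  Recommended
    search ranges (the study protocol's grid): hidden sizes 4-400, L1 in
    [5e-6, 5e-4] or 0, L2 in [5e-7, 5e-5] or 0, dropout fractions up to
    0.5, epochs 200-600.
    """

    n_inputs: int
    hidden_sizes: tuple[int, int] = (16, 16)
    activation: str = "tanh"
    task: str = "classification"  # classification | regression
    n_classes: int = 2
    l1: float = 0.0
    l2: float = 0.0
    input_dropout: float = 0.0
    hidden_dropout: float = 0.0
    epochs: int = 300
    learning_rate: float = 0.02
    rate_annealing: float = 1e-6  # lr_t = lr / (1 + t * annealing), t = updates
    momentum: float = 0.9
    batch_size: int = 16
    maxout_channels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise SpecError("n_inputs must be positive")
        if len(self.hidden_sizes) != 2:
            raise SpecError("exactly two hidden layers are required")
        if any(not 1 <= h <= 400 for h in self.hidden_sizes):
            raise SpecError("hidden sizes must lie in [1, 400]")
        if self.activation not in ACTIVATIONS:
            raise SpecError(f"activation must be one of {ACTIVATIONS}")
        if self.task not in ("classification", "regression"):
            raise SpecError("task must be 'classification' or 'regression'")
        if self.task == "classification" and self.n_classes < 2:
            raise SpecError("classification needs >= 2 classes")
        if not 0.0 <= self.input_dropout <= 0.5 or not 0.0 <= self.hidden_dropout <= 0.5:
            raise SpecError("dropout fractions must lie in [0, 0.5]")
        if self.l1 < 0 or self.l2 < 0:
            raise SpecError("regularization coefficients must be nonnegative")
        if self.epochs < 1:
            raise SpecError("epochs must be positive")
        if self.maxout_channels < 2:
            raise SpecError("maxout needs >= 2 channels")

    @property
    def n_outputs(self) -> int:
        return self.n_classes if self.task == "classification" else 1

    def sort_key(self) -> tuple:
        """Deterministic tie-break key: smaller total hidden size, then repr."""
        return (sum(self.hidden_sizes), repr(self))


@dataclass
class NetworkModel:
    """Weights, biases and input standardization of one (possibly fitted) net."""

    spec: NetworkSpec
    weights: list[np.ndarray]  # [W1, W2, W3]
    biases: list[np.ndarray]  # [b1, b2, b3]
    input_mean: np.ndarray | None = None
    input_sd: np.ndarray | None = None
    history: list[float] = field(default_factory=list)
    fitted: bool = False

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.input_mean is None:
            raise RuntimeError("standardization parameters not fitted")
        return (X - self.input_mean) / self.input_sd


def _uniform_init(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_network(spec: NetworkSpec) -> NetworkModel:
    """Initialize weights uniformly scaled by fan-in/fan-out; biases zero."""
    rng = np.random.default_rng(spec.seed)
    h1, h2 = spec.hidden_sizes
    n_out = spec.n_outputs
    C = spec.maxout_channels
    if spec.activation == "maxout":
        W1 = _uniform_init(rng, (spec.n_inputs, h1, C), spec.n_inputs, h1)
        b1 = np.zeros((h1, C))
        W2 = _uniform_init(rng, (h1, h2, C), h1, h2)
        b2 = np.zeros((h2, C))
    else:
        W1 = _uniform_init(rng, (spec.n_inputs, h1), spec.n_inputs, h1)
        b1 = np.zeros(h1)
        W2 = _uniform_init(rng, (h1, h2), h1, h2)
        b2 = np.zeros(h2)
    W3 = _uniform_init(rng, (h2, n_out), h2, n_out)
    b3 = np.zeros(n_out)
    return NetworkModel(spec=spec, weights=[W1, W2, W3], biases=[b1, b2, b3])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _hidden_layer(
    a_prev: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str
) -> tuple[np.ndarray, np.ndarray | None]:
    """Return (activated output, cache for backprop)."""
    if activation == "maxout":
        # z: (n, h, C)
        z = np.einsum("ni,ihc->nhc", a_prev, W) + b
        amax = z.argmax(axis=2)
        h = np.take_along_axis(z, amax[:, :, None], axis=2)[:, :, 0]
        return h, amax
    z = a_prev @ W + b
    if activation == "tanh":
        return np.tanh(z), None
    # rectifier
    return np.maximum(z, 0.0), None


def forward(
    model: NetworkModel,
    X: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Forward pass on already-standardized inputs.

    Returns a cache of layer activations (and dropout masks / maxout
    channel choices when applicable).  Dropout is "inverted": retained
    activations are rescaled at training time so inference needs none.
    """
    spec = model.spec
    W1, W2, W3 = model.weights
    b1, b2, b3 = model.biases
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.n_inputs:
        raise ValueError(
            f"expected {spec.n_inputs} input features, got {X.shape[1]}"
        )
    cache: dict = {"X": X}

    a0 = X
    if training and spec.input_dropout > 0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - spec.input_dropout
        mask0 = (rng.random(a0.shape) < keep) / keep
        a0 = a0 * mask0
        cache["mask0"] = mask0
    cache["a0"] = a0

    h1, ch1 = _hidden_layer(a0, W1, b1, spec.activation)
    cache["ch1"] = ch1
    if training and spec.hidden_dropout > 0:
        keep = 1.0 - spec.hidden_dropout
        mask1 = (rng.random(h1.shape) < keep) / keep
        h1 = h1 * mask1
        cache["mask1"] = mask1
    cache["h1"] = h1

    h2, ch2 = _hidden_layer(h1, W2, b2, spec.activation)
    cache["ch2"] = ch2
    if training and spec.hidden_dropout > 0:
        keep = 1.0 - spec.hidden_dropout
        mask2 = (rng.random(h2.shape) < keep) / keep
        h2 = h2 * mask2
        cache["mask2"] = mask2
    cache["h2"] = h2

    z3 = h2 @ W3 + b3
    cache["z3"] = z3
    if spec.task == "classification":
        cache["output"] = _softmax(z3)
    else:
        cache["output"] = z3[:, 0]
    return cache


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((y.size, k))
    out[np.arange(y.size), y] = 1.0
    return out


def _data_loss(spec: NetworkSpec, output: np.ndarray, y: np.ndarray) -> float:
    if spec.task == "classification":
        p = np.clip(output[np.arange(y.size), y], P_FLOOR, None)
        return float(-np.mean(np.log(p)))
    return float(np.mean((output - y) ** 2))


def _reg_loss(spec: NetworkSpec, weights: Sequence[np.ndarray]) -> float:
    total = 0.0
    for W in weights:
        if spec.l1:
            total += spec.l1 * np.abs(W).sum()
        if spec.l2:
            total += spec.l2 * np.square(W).sum()
    return float(total)


def loss(model: NetworkModel, X: np.ndarray, y: np.ndarray) -> float:
    """Mean data loss (cross-entropy / MSE) plus L1 and L2 weight penalties."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty batch")
    cache = forward(model, X, training=False)
    return _data_loss(model.spec, cache["output"], y) + _reg_loss(
        model.spec, model.weights
    )


def _backprop(
    model: NetworkModel, cache: dict, y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the regularized loss w.r.t. weights and biases."""
    spec = model.spec
    W1, W2, W3 = model.weights
    n = cache["a0"].shape[0]
    output = cache["output"]

    if spec.task == "classification":
        delta3 = (output - _one_hot(y, spec.n_classes)) / n  # (n, k)
    else:
        delta3 = (2.0 * (output - y) / n)[:, None]  # (n, 1)

    h2, h1, a0 = cache["h2"], cache["h1"], cache["a0"]
    gW3 = h2.T @ delta3
    gb3 = delta3.sum(axis=0)

    dh2 = delta3 @ W3.T  # (n, h2)
    if "mask2" in cache:
        dh2 = dh2 * cache["mask2"]
    gW2, gb2, dh1 = _hidden_backward(spec, a_prev=h1, W=W2, ch=cache["ch2"], h=cache["h2"], mask=cache.get("mask2"), delta=dh2)
    if "mask1" in cache:
        dh1 = dh1 * cache["mask1"]
    gW1, gb1, _ = _hidden_backward(spec, a_prev=a0, W=W1, ch=cache["ch1"], h=cache["h1"], mask=cache.get("mask1"), delta=dh1)

    for g, W in ((gW1, W1), (gW2, W2), (gW3, W3)):
        if spec.l1:
            g += spec.l1 * np.sign(W)
        if spec.l2:
            g += 2.0 * spec.l2 * W
    return [gW1, gW2, gW3], [gb1, gb2, gb3]


def _hidden_backward(
    spec: NetworkSpec,
    a_prev: np.ndarray,
    W: np.ndarray,
    ch: np.ndarray | None,
    h: np.ndarray,
    mask: np.ndarray | None,
    delta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backward through one hidden layer.

    ``delta`` is dLoss/d(layer output after dropout masking upstream);
    ``h`` is the layer output *after* dropout.  Returns gradients for W
    and b and the delta propagated to the previous layer's output.
    """
    if spec.activation == "maxout":
        # route delta to the argmax channel
        n, nh = delta.shape
        C = spec.maxout_channels
        dz = np.zeros((n, nh, C))
        np.put_along_axis(dz, ch[:, :, None], delta[:, :, None], axis=2)
        gW = np.einsum("ni,nhc->ihc", a_prev, dz)
        gb = dz.sum(axis=0)
        dprev = np.einsum("nhc,ihc->ni", dz, W)
        return gW, gb, dprev
    # recover pre-dropout activation for the derivative
    act = h if mask is None else np.where(mask > 0, h / np.where(mask > 0, mask, 1.0), 0.0)
    if spec.activation == "tanh":
        dz = delta * (1.0 - act**2)
    else:  # rectifier
        dz = delta * (act > 0)
    gW = a_prev.T @ dz
    gb = dz.sum(axis=0)
    dprev = dz @ W.T
    return gW, gb, dprev


def train_sgd(
    model: NetworkModel,
    X: np.ndarray,
    y: np.ndarray,
    standardize: bool = True,
) -> NetworkModel:
    """Fit by minibatch SGD with Nesterov momentum; deterministic per seed.

    Standardization parameters (per-feature mean and sd) are fitted on
    the given training data and stored on the model.  The training loss
    (regularized, dropout off) is recorded once per epoch.  Non-finite
    loss raises :class:`DivergenceError` advising a lower learning rate.
    """
    spec = model.spec
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if spec.task == "classification":
        y = y.astype(int)
        if y.min() < 0 or y.max() >= spec.n_classes:
            raise ValueError("labels out of range for the declared classes")
    else:
        y = y.astype(float)

    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        model.input_mean = mean
        model.input_sd = sd
        Xs = (X - mean) / sd
    else:
        model.input_mean = np.zeros(X.shape[1])
        model.input_sd = np.ones(X.shape[1])
        Xs = X

    rng = np.random.default_rng(spec.seed + 1)
    vel_w = [np.zeros_like(W) for W in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    mu = spec.momentum
    n = Xs.shape[0]
    batch = min(spec.batch_size, n)
    t = 0
    model.history = []
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            lr = spec.learning_rate / (1.0 + t * spec.rate_annealing)
            t += 1
            cache = forward(model, Xs[idx], training=True, rng=rng)
            gw, gb = _backprop(model, cache, y[idx])
            for i in range(3):
                v_prev = vel_w[i]
                vel_w[i] = mu * v_prev - lr * gw[i]
                model.weights[i] += -mu * v_prev + (1.0 + mu) * vel_w[i]
                v_prev = vel_b[i]
                vel_b[i] = mu * v_prev - lr * gb[i]
                model.biases[i] += -mu * v_prev + (1.0 + mu) * vel_b[i]
        epoch_loss = _data_loss(
            spec, forward(model, Xs, training=False)["output"], y
        ) + _reg_loss(spec, model.weights)
        if not np.isfinite(epoch_loss):
            raise DivergenceError(
                "training loss is non-finite; lower the learning rate"
            )
        model.history.append(epoch_loss)
    model.fitted = True
    return model


def predict(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    """Inference: class-probability rows (classification) or values."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = model.standardize(X)
    return forward(model, Xs, training=False)["output"]


def predict_labels(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    probs = predict(model, X)
    return probs.argmax(axis=1)


def metrics(
    predictions: np.ndarray, truth: np.ndarray, task: str
) -> dict[str, float]:
    """Standard evaluation metrics.

    Classification: misclassification rate (argmax vs truth) and log
    loss.  Regression: MSE, r^2 of predictions against observations and
    the adjusted r^2 for a single predictor,
    ``1 - (1 - r^2) (n - 1) / (n - 2)``.
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if task == "classification":
        labels = predictions.argmax(axis=1)
        p_true = np.clip(
            predictions[np.arange(truth.size), truth.astype(int)], P_FLOOR, None
        )
        return {
            "misclassification": float(np.mean(labels != truth)),
            "log_loss": float(-np.mean(np.log(p_true))),
        }
    n = truth.size
    if n < 3:
        raise ValueError("adjusted r^2 requires at least 3 observations")
    resid = truth - predictions
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return {
        "mse": float(np.mean(resid**2)),
        "r2": r2,
        "adjusted_r2": adj,
    }


@dataclass
class CVResult:
    """Pooled holdout predictions and metrics from k-fold cross-validation."""

    k: int
    holdout_indices: list[np.ndarray]
    predictions: np.ndarray  # aligned to the input row order
    truth: np.ndarray
    metrics: dict[str, float]
    confusion: pd.DataFrame | None = None


def _cv_splitter(spec: NetworkSpec, y: np.ndarray, k: int):
    if spec.task == "classification":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() >= k:
            return StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
        warnings.warn(
            "class sizes too small for stratification; using unstratified folds"
        )
    return KFold(n_splits=k, shuffle=True, random_state=spec.seed)


def kfold_cv(
    spec: NetworkSpec, X: np.ndarray, y: np.ndarray, k: int = 7
) -> CVResult:
    """k-fold cross-validation (default sevenfold: ~86% train / 14% holdout).

    Each fold's model is trained from scratch on the complement
    (standardization refitted per fold); holdout predictions are pooled
    and scored once, so every sample contributes exactly one prediction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    splitter = _cv_splitter(spec, y, k)
    if spec.task == "classification":
        preds = np.zeros((n, spec.n_classes))
        y_int = y.astype(int)
        split_iter = splitter.split(X, y_int)
    else:
        preds = np.zeros(n)
        split_iter = splitter.split(X)
    holdouts = []
    for fold, (train_idx, test_idx) in enumerate(split_iter):
        fold_spec = replace(spec, seed=spec.seed + 1000 * (fold + 1))
        if spec.task == "classification" and len(np.unique(y[train_idx])) < spec.n_classes:
            warnings.warn(f"fold {fold}: a class is absent from the training part")
        model = train_sgd(init_network(fold_spec), X[train_idx], y[train_idx])
        preds[test_idx] = predict(model, X[test_idx])
        holdouts.append(test_idx)
    m = metrics(preds, y, spec.task)
    confusion = None
    if spec.task == "classification":
        labels = preds.argmax(axis=1)
        confusion = pd.crosstab(
            pd.Series(y.astype(int), name="true"),
            pd.Series(labels, name="predicted"),
            dropna=False,
        )
    return CVResult(
        k=k,
        holdout_indices=holdouts,
        predictions=preds,
        truth=y,
        metrics=m,
        confusion=confusion,
    )


def replace_spec(spec: NetworkSpec, **changes) -> NetworkSpec:
    """Copy a spec with the given fields replaced (validation re-runs)."""
    return replace(spec, **changes)


def expand_grid(base: NetworkSpec, **param_lists) -> list[NetworkSpec]:
    """Cartesian expansion of hyperparameter lists around a base spec."""
    keys = list(param_lists)
    specs = []
    for combo in itertools.product(*(param_lists[k] for k in keys)):
        specs.append(replace(base, **dict(zip(keys, combo))))
    return specs


def grid_search(
    grid: Sequence[NetworkSpec],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 7,
    scoring: str | None = None,
) -> tuple[NetworkSpec, NetworkModel, pd.DataFrame]:
    """Evaluate every grid point by k-fold CV; refit the winner on all data.

    The score is log loss for classification and MSE for regression
    (overridable via ``scoring`` naming any CV metric).  Ties break
    toward the smaller total hidden size, then lexicographically on the
    spec repr.  Returns (best spec, refit model, leaderboard).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    rows = []
    results: list[tuple[float, tuple, NetworkSpec]] = []
    for spec in grid:
        key = scoring or ("log_loss" if spec.task == "classification" else "mse")
        try:
            cv = kfold_cv(spec, X, y, k=k)
        except DivergenceError:
            rows.append({"spec": repr(spec), "score": np.nan, "diverged": True})
            continue
        score = cv.metrics[key]
        rows.append(
            {"spec": repr(spec), "score": score, "diverged": False, **cv.metrics}
        )
        results.append((score, spec.sort_key(), spec))
    if not results:
        raise DivergenceError("every grid point diverged")
    results.sort(key=lambda r: (r[0], r[1]))
    best_spec = results[0][2]
    best_model = train_sgd(init_network(best_spec), X, y)
    leaderboard = pd.DataFrame(rows).sort_values("score", kind="mergesort")
    return best_spec, best_model, leaderboard.reset_index(drop=True)


# ---------------------------------------------------------------------------
# weight/bias export
# ---------------------------------------------------------------------------

def export_weights_biases(model: NetworkModel) -> dict:
    """Lossless bundle of weights, biases and standardization parameters."""
    bundle = {
        "spec": asdict(model.spec),
        "W1": model.weights[0],
        "W2": model.weights[1],
        "W3": model.weights[2],
        "b1": model.biases[0],
        "b2": model.biases[1],
        "b3": model.biases[2],
        "input_mean": model.input_mean,
        "input_sd": model.input_sd,
        "fitted": model.fitted,
    }
    return bundle


def model_from_bundle(bundle: dict) -> NetworkModel:
    spec_dict = dict(bundle["spec"])
    spec_dict["hidden_sizes"] = tuple(spec_dict["hidden_sizes"])
    spec = NetworkSpec(**spec_dict)
    return NetworkModel(
        spec=spec,
        weights=[np.asarray(bundle["W1"]), np.asarray(bundle["W2"]), np.asarray(bundle["W3"])],
        biases=[np.asarray(bundle["b1"]), np.asarray(bundle["b2"]), np.asarray(bundle["b3"])],
        input_mean=None if bundle["input_mean"] is None else np.asarray(bundle["input_mean"]),
        input_sd=None if bundle["input_sd"] is None else np.asarray(bundle["input_sd"]),
        fitted=bool(bundle["fitted"]),
    )


def save_model(model: NetworkModel, path: str | Path) -> None:
    """Single-file container: JSON header plus binary arrays (.npz)."""
    bundle = export_weights_biases(model)
    arrays = {
        k: v
        for k, v in bundle.items()
        if isinstance(v, np.ndarray)
    }
    header = json.dumps({"spec": bundle["spec"], "fitted": bundle["fitted"]})
    np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> NetworkModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"].tobytes()).decode())
        bundle = {
            "spec": header["spec"],
            "fitted": header["fitted"],
            "W1": data["W1"],
            "W2": data["W2"],
            "W3": data["W3"],
            "b1": data["b1"],
            "b2": data["b2"],
            "b3": data["b3"],
            "input_mean": data["input_mean"] if "input_mean" in data else None,
            "input_sd": data["input_sd"] if "input_sd" in data else None,
        }
    return model_from_bundle(bundle)
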