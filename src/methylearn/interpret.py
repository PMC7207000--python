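"""Interpretation of fitted networks: importance, elimination, response curves.

Three complementary views of what a fitted two-hidden-layer network
learned from its CpG inputs:

* **Weight-based variable importance** (Gedeon-style): absolute weights
  of each layer are column-normalized into contribution fractions and
  chained through the two hidden layers; an input's score is its total
  share of absolute-weight flow into the second hidden layer.  Scores
  are nonnegative and sum to one, and are invariant to rescaling any
  layer by a positive constant.
* **Backward elimination**: repeatedly refit (grid search + CV) on the
  current input set, rank inputs by importance, and keep the top ``m``
  for the next step of a strictly decreasing schedule.
* **Profile-method response curves**: for each input, set it to each of
  the 99 empirical percentiles (0.01..0.99) of its training values
  while all remaining inputs co-move at a shared background percentile
  (also 0.01..0.99), and record the network output for each of the
  99 x 99 = 9801 combinations.  Plotting output activation against the
  focal methylation level reveals the methylation intervals the model
  associates with each class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .nn import NetworkModel, NetworkSpec, predict

N_QUANTILES = 99


@dataclass
class ImportanceRanking:
    """Normalized per-input importance scores (sum to one) with rank order."""

    input_ids: list[str]
    scores: np.ndarray
    order: np.ndarray  # indices, descending score, ties by input index

    def top(self, m: int) -> list[str]:
        return [self.input_ids[i] for i in self.order[:m]]

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.input_ids, name="importance")


def _abs_weight(W: np.ndarray) -> np.ndarray:
    """Absolute weight matrix; maxout channels collapse to their max |w|."""
    A = np.abs(W)
    if A.ndim == 3:
        A = A.max(axis=2)
    return A


def _contribution(A: np.ndarray) -> np.ndarray:
    """Column-normalize; all-zero columns contribute nothing."""
    colsum = A.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(colsum > 0, A / np.where(colsum > 0, colsum, 1.0), 0.0)
    return P


def gedeon_importance(
    model: NetworkModel, input_ids: Sequence[str] | None = None
) -> ImportanceRanking:
    """Importance of each input through the two hidden layers.

    ``P1[i, j] = |W1[i, j]| / sum_i' |W1[i', j]|`` and likewise
    ``P2[j, k]`` for the second layer; the raw importance of input ``i``
    is ``sum_k sum_j P1[i, j] P2[j, k]``, normalized to sum to one.
    The output layer is deliberately not traversed (an option for
    sensitivity checks extends the chain through W3 via
    :func:`gedeon_importance_through_output`).
    """
    P1 = _contribution(_abs_weight(model.weights[0]))
    P2 = _contribution(_abs_weight(model.weights[1]))
    raw = (P1 @ P2).sum(axis=1)
    total = raw.sum()
    scores = raw / total if total > 0 else np.full_like(raw, 1.0 / raw.size)
    if input_ids is None:
        input_ids = [f"input_{i}" for i in range(scores.size)]
    order = np.argsort(-scores, kind="stable")
    return ImportanceRanking(list(input_ids), scores, order)


def gedeon_importance_through_output(
    model: NetworkModel, input_ids: Sequence[str] | None = None
) -> ImportanceRanking:
    """Variant extending the contribution chain through the output layer."""
    P1 = _contribution(_abs_weight(model.weights[0]))
    P2 = _contribution(_abs_weight(model.weights[1]))
    P3 = _contribution(_abs_weight(model.weights[2]))
    raw = (P1 @ P2 @ P3).sum(axis=1)
    scores = raw / raw.sum()
    if input_ids is None:
        input_ids = [f"input_{i}" for i in range(scores.size)]
    order = np.argsort(-scores, kind="stable")
    return ImportanceRanking(list(input_ids), scores, order)


@dataclass
class EliminationStep:
    n_inputs: int
    selection: list[str]
    best_spec: NetworkSpec
    cv_metrics: dict[str, float]
    importance: ImportanceRanking


@dataclass
class EliminationTrace:
    """Record of a backward-elimination run, largest model first."""

    steps: list[EliminationStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def summary(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            rows.append({"n_inputs": s.n_inputs, **s.cv_metrics})
        return pd.DataFrame(rows)


def fractional_schedule(n: int, fraction: float = 0.05, stop: int = 1) -> list[int]:
    """Schedule removing ``fraction`` of the inputs (floor) at each step."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    schedule = [n]
    current = n
    while current > stop:
        nxt = int(np.floor(current * (1.0 - fraction)))
        if nxt >= current:
            nxt = current - 1
        if nxt < stop:
            break
        schedule.append(nxt)
        current = nxt
    return schedule


def backward_eliminate(
    X: pd.DataFrame,
    y: np.ndarray,
    initial_selection: Sequence[str],
    schedule: Sequence[int],
    trainer: Callable[[pd.DataFrame, np.ndarray], tuple[NetworkSpec, NetworkModel, dict]],
) -> EliminationTrace:
    """Iteratively shrink the input set along a strictly decreasing schedule.

    ``trainer(X_subset, y)`` must return ``(best_spec, best_model,
    cv_metrics)`` — typically a closure over a hyperparameter grid
    search with cross-validation.  At each schedule value the model is
    refit on the surviving inputs; the next step keeps the top inputs of
    the current model's importance ranking.
    """
    schedule = list(schedule)
    selection = list(initial_selection)
    if not schedule:
        raise ValueError("empty schedule")
    if schedule[0] != len(selection):
        raise ValueError(
            f"schedule must start at the initial selection size "
            f"({len(selection)}), got {schedule[0]}"
        )
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly decreasing")
    trace = EliminationTrace()
    for step_i, m in enumerate(schedule):
        if m > len(selection):
            raise ValueError(f"schedule value {m} exceeds current size {len(selection)}")
        if m < len(selection):
            prev = trace.steps[-1]
            keep = set(prev.importance.top(m))
            selection = [pid for pid in selection if pid in keep]
        Xs = X.loc[:, selection]
        best_spec, best_model, cv_metrics = trainer(Xs, y)
        ranking = gedeon_importance(best_model, input_ids=selection)
        trace.steps.append(
            EliminationStep(
                n_inputs=len(selection),
                selection=list(selection),
                best_spec=best_spec,
                cv_metrics=dict(cv_metrics),
                importance=ranking,
            )
        )
    return trace


def profile_curves(
    model: NetworkModel,
    training_inputs: pd.DataFrame,
    n_quantiles: int = N_QUANTILES,
) -> pd.DataFrame:
    """Quantile-permutation response curves for every model input.

    For each focal input, its value is swept over the ``n_quantiles``
    empirical percentiles (linear interpolation) of its training
    column; at each focal value the remaining inputs are jointly set to
    their own q-th percentile for q = 0.01 .. 0.99, giving
    ``n_quantiles ** 2`` input vectors per focal input.  Each vector is
    standardized by the model's stored parameters inside ``predict``.

    Returns a long-format frame with columns ``input_id, qf,
    focal_value, qb`` plus one activation column per output neuron
    (``p_<class>`` for classification, ``output`` for regression).
    Constant training columns are flagged in the ``constant_input``
    column (their percentiles all collapse to the single value).
    """
    spec = model.spec
    cols = list(training_inputs.columns)
    if len(cols) != spec.n_inputs:
        raise ValueError(
            f"training matrix has {len(cols)} columns, model expects {spec.n_inputs}"
        )
    if training_inputs.isna().any().any():
        raise ValueError("training matrix must be complete (imputed)")
    qs = np.arange(1, n_quantiles + 1) / 100.0
    quants = np.quantile(
        training_inputs.to_numpy(dtype=float), qs, axis=0, method="linear"
    )  # (n_quantiles, p)
    constant = training_inputs.nunique().to_numpy() == 1
    frames = []
    p = len(cols)
    for i, pid in enumerate(cols):
        # outer loop over focal quantiles, inner over the shared background
        # quantile at which all remaining inputs co-move
        Xmat = np.tile(quants, (n_quantiles, 1))  # (nq*nq, p): inner = qb sweep
        focal_vals = np.repeat(quants[:, i], n_quantiles)
        Xmat[:, i] = focal_vals
        out = predict(model, Xmat)
        frame = pd.DataFrame(
            {
                "input_id": pid,
                "qf": np.repeat(qs, n_quantiles),
                "focal_value": focal_vals,
                "qb": np.tile(qs, n_quantiles),
                "constant_input": bool(constant[i]),
            }
        )
        if spec.task == "classification":
            for c in range(spec.n_classes):
                frame[f"p_{c}"] = out[:, c]
        else:
            frame["output"] = out
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def diagram_data(model: NetworkModel, ranking: ImportanceRanking) -> dict:
    """Serializable neural-interpretation-diagram specification.

    Nodes: inputs (ordered by descending importance), hidden and output
    neurons, and one bias node per layer.  Edges carry the signed weight
    magnitude; positive weights are stimulatory, negative inhibitory.
    Maxout weights are represented by the channel with the largest
    absolute value (sign preserved).
    """

    def _collapse(W: np.ndarray) -> np.ndarray:
        if W.ndim == 3:
            idx = np.abs(W).argmax(axis=2)
            return np.take_along_axis(W, idx[:, :, None], axis=2)[:, :, 0]
        return W

    def _collapse_bias(b: np.ndarray) -> np.ndarray:
        if b.ndim == 2:
            idx = np.abs(b).argmax(axis=1)
            return b[np.arange(b.shape[0]), idx]
        return b

    W1, W2, W3 = (_collapse(W) for W in model.weights)
    b1, b2, b3 = (_collapse_bias(b) for b in model.biases)
    ordered_inputs = [ranking.input_ids[i] for i in ranking.order]
    nodes = (
        [{"id": f"I:{pid}", "layer": "input", "importance": float(ranking.scores[i])}
         for i, pid in zip(ranking.order, ordered_inputs)]
        + [{"id": f"H1:{j}", "layer": "hidden1"} for j in range(W1.shape[1])]
        + [{"id": f"H2:{k}", "layer": "hidden2"} for k in range(W2.shape[1])]
        + [{"id": f"O:{o}", "layer": "output"} for o in range(W3.shape[1])]
        + [{"id": f"B:{l}", "layer": "bias"} for l in (1, 2, 3)]
    )
    edges = []

    def _add(src: str, dst: str, w: float) -> None:
        edges.append(
            {
                "source": src,
                "target": dst,
                "weight": float(w),
                "sign": "stimulatory" if w >= 0 else "inhibitory",
            }
        )

    for i, pid in enumerate(ranking.input_ids):
        for j in range(W1.shape[1]):
            _add(f"I:{pid}", f"H1:{j}", W1[i, j])
    for j in range(W2.shape[0]):
        for k in range(W2.shape[1]):
            _add(f"H1:{j}", f"H2:{k}", W2[j, k])
    for k in range(W3.shape[0]):
        for o in range(W3.shape[1]):
            _add(f"H2:{k}", f"O:{o}", W3[k, o])
    for j, v in enumerate(b1):
        _add("B:1", f"H1:{j}", v)
    for k, v in enumerate(b2):
        _add("B:2", f"H2:{k}", v)
    for o, v in enumerate(b3):
        _add("B:3", f"O:{o}", v)
    return {"nodes": nodes, "edges": edges, "importance_order": ordered_inputs}
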