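"""Per-vowel age classifiers and the linear vowel gate.

The age classifier is a single-hidden-layer feed-forward network (SLFN)
trained as an extreme learning machine (ELM): input weights ``w_i`` and
biases ``b_i`` are random, the hidden output matrix is
``H[j, i] = g(w_i . x_j + b_i)``, and the output weights solve the linear
least-squares problem ``H beta = T`` analytically via the Moore-Penrose
pseudo-inverse (minimum-norm among minimizers).

The self-adaptive variant (SaELM) keeps the analytic output solve but
optimizes the input weights and biases with differential evolution using the
DE/rand-to-best/2 mutation strategy; fitness is the root-mean-square error of
the one-hot targets on a stratified validation split of the training data.

The vowel gate is a one-vs-one maximum-margin linear classifier that routes
an unlabeled utterance to the matching per-vowel age model.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

__all__ = [
    "ACTIVATIONS",
    "activation_fn",
    "SLFNModel",
    "SaELMParams",
    "GateModel",
    "one_hot_targets",
    "hidden_output_matrix",
    "elm_fit",
    "elm_predict",
    "elm_predict_labels",
    "saelm_fit",
    "fit_vowel_gate",
    "predict_vowel",
    "save_model",
    "load_model",
]

ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "sin": np.sin,
    "hardlim": lambda z: np.where(z >= 0, 1.0, 0.0),
    # identity is a test hook: H collapses to the affine map itself
    "identity": lambda z: z,
}


def activation_fn(name: str, z):
    """Apply a named activation; hardlim maps z >= 0 to 1, else 0."""
    try:
        g = ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None
    return g(np.asarray(z, dtype=np.float64))


@dataclass
class SLFNModel:
    """A trained single-hidden-layer network.

    ``scale_offset``/``scale_factor`` hold the per-dimension affine map that
    sends training features into [-1, 1]; it is re-applied at prediction.
    """

    input_weights: np.ndarray  # (n_hidden, n_features)
    biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden, n_classes)
    activation: str
    class_labels: np.ndarray  # (n_classes,)
    scale_offset: np.ndarray  # (n_features,)
    scale_factor: np.ndarray  # (n_features,)
    fitness_history: list[float] | None = None

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        n_hidden, n_features = self.input_weights.shape
        if self.biases.shape != (n_hidden,):
            raise ValueError("bias vector does not match hidden size")
        if self.output_weights.shape[0] != n_hidden:
            raise ValueError("output weights do not match hidden size")
        if len(self.class_labels) != self.output_weights.shape[1]:
            raise ValueError("class labels do not match output width")

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]


@dataclass(frozen=True)
class SaELMParams:
    """Differential-evolution settings for SaELM.

    Defaults follow the standard configuration for this task: 40 individuals,
    15 generations, amplification F = 1, crossover rate 0.5, the
    DE/rand-to-best/2 strategy, and 60 hidden neurons.
    """

    population_size: int = 40
    generations: int = 15
    amplification: float = 1.0
    crossover_rate: float = 0.5
    mutation_strategy: str = "DE/rand-to-best/2"
    n_hidden: int = 60
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 5:
            raise ValueError(
                "DE/rand-to-best/2 needs >= 5 distinct indices: "
                f"population_size={self.population_size} too small"
            )
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.mutation_strategy != "DE/rand-to-best/2":
            raise ValueError("only the DE/rand-to-best/2 strategy is supported")


def _validate_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    return X


def _fit_scaling(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Affine map to [-1, 1] per dimension from training min/max."""
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    factor = np.where(span > 0, 2.0 / np.where(span > 0, span, 1.0), 0.0)
    offset = np.where(span > 0, -(hi + lo) / np.where(span > 0, span, 1.0), 0.0)
    return offset, factor


def _apply_scaling(X: np.ndarray, offset: np.ndarray, factor: np.ndarray) -> np.ndarray:
    return X * factor + offset


def one_hot_targets(labels: Sequence, class_labels: np.ndarray) -> np.ndarray:
    """N x m one-hot target matrix (1 at the true class, 0 elsewhere)."""
    index = {c: j for j, c in enumerate(class_labels)}
    T = np.zeros((len(labels), len(class_labels)))
    for i, lab in enumerate(labels):
        T[i, index[lab]] = 1.0
    return T


def hidden_output_matrix(X: np.ndarray, model: SLFNModel) -> np.ndarray:
    """H[j, i] = g(w_i . x_j + b_i) on already-scaled features."""
    X = _validate_features(X)
    if X.shape[1] != model.input_weights.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.input_weights.shape[1]})"
        )
    return activation_fn(model.activation, X @ model.input_weights.T + model.biases)


def _solve_output_weights(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    # minimum-norm least-squares solution of H beta = T (beta = H^+ T)
    beta, *_ = np.linalg.lstsq(H, T, rcond=None)
    return beta


def elm_fit(
    X: np.ndarray,
    labels: Sequence,
    n_hidden: int,
    activation: str = "sigmoid",
    seed: int = 0,
) -> SLFNModel:
    """Train an ELM: random input layer, analytic output solve.

    Input weights and biases are uniform on [-1, 1]; features are affinely
    scaled to [-1, 1] per dimension using training min/max, and the scaling is
    stored on the model for prediction.
    """
    X = _validate_features(X)
    class_labels = np.unique(np.asarray(labels))
    if X.shape[0] < 2 or class_labels.size < 2:
        raise ValueError("need at least 2 samples and 2 distinct classes")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    offset, factor = _fit_scaling(X)
    model = SLFNModel(
        input_weights=W,
        biases=b,
        output_weights=np.zeros((n_hidden, class_labels.size)),
        activation=activation,
        class_labels=class_labels,
        scale_offset=offset,
        scale_factor=factor,
    )
    H = hidden_output_matrix(_apply_scaling(X, offset, factor), model)
    T = one_hot_targets(labels, class_labels)
    model.output_weights = _solve_output_weights(H, T)
    return model


def elm_predict(model: SLFNModel, X: np.ndarray) -> np.ndarray:
    """Raw N x m score matrix H . beta for (unscaled) features."""
    X = _validate_features(np.atleast_2d(X))
    H = hidden_output_matrix(
        _apply_scaling(X, model.scale_offset, model.scale_factor), model
    )
    return H @ model.output_weights


def elm_predict_labels(model: SLFNModel, X: np.ndarray) -> np.ndarray:
    """Argmax decoding; ties resolve to the lowest class index."""
    scores = elm_predict(model, X)
    return model.class_labels[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# SaELM: differential evolution over the input layer


def _unpack_individual(
    vec: np.ndarray, n_hidden: int, n_features: int
) -> tuple[np.ndarray, np.ndarray]:
    W = vec[: n_hidden * n_features].reshape(n_hidden, n_features)
    b = vec[n_hidden * n_features :]
    return W, b


def saelm_fit(
    X: np.ndarray,
    labels: Sequence,
    params: SaELMParams | None = None,
    activation: str = "sigmoid",
) -> SLFNModel:
    """Self-adaptive ELM: evolve the input layer, solve the output layer.

    Each DE individual is the concatenated input-weight matrix and bias
    vector.  Fitness is validation RMSE after the analytic output solve;
    selection is greedy, with ties broken by smaller output-weight norm, so
    the best fitness is non-increasing across generations.  The returned
    model uses the winning input layer with output weights re-solved on the
    full training set (at ``generations=0`` this is exactly the
    best-of-initial-population ELM).
    """
    params = params or SaELMParams()
    X = _validate_features(X)
    class_labels = np.unique(np.asarray(labels))
    if class_labels.size < 2:
        raise ValueError("need at least 2 distinct classes")
    labels = np.asarray(labels)
    offset, factor = _fit_scaling(X)
    Xs = _apply_scaling(X, offset, factor)
    T = one_hot_targets(labels, class_labels)

    # stratified split where feasible; tiny training sets (fewer validation
    # slots than classes, or singleton classes) fall back to a plain shuffle
    n_val = int(np.ceil(params.validation_fraction * X.shape[0]))
    counts = np.unique(labels, return_counts=True)[1]
    stratify = labels if (n_val >= class_labels.size and counts.min() >= 2) else None
    idx_train, idx_val = train_test_split(
        np.arange(X.shape[0]),
        test_size=params.validation_fraction,
        stratify=stratify,
        random_state=params.seed % (2**32),
    )
    X_tr, T_tr = Xs[idx_train], T[idx_train]
    X_val, T_val = Xs[idx_val], T[idx_val]

    g = ACTIVATIONS[activation]
    n_hidden, n_features = params.n_hidden, X.shape[1]
    dim = n_hidden * (n_features + 1)
    rng = np.random.default_rng(params.seed)

    def evaluate(vec: np.ndarray) -> tuple[float, float]:
        W, b = _unpack_individual(vec, n_hidden, n_features)
        H_tr = g(X_tr @ W.T + b)
        beta = _solve_output_weights(H_tr, T_tr)
        H_val = g(X_val @ W.T + b)
        resid = H_val @ beta - T_val
        rmse = float(np.sqrt(np.mean(resid**2)))
        return rmse, float(np.linalg.norm(beta))

    population = rng.uniform(-1.0, 1.0, size=(params.population_size, dim))
    fitness = np.empty(params.population_size)
    beta_norm = np.empty(params.population_size)
    for i, vec in enumerate(population):
        fitness[i], beta_norm[i] = evaluate(vec)

    def best_index() -> int:
        order = np.lexsort((beta_norm, fitness))
        return int(order[0])

    history = [float(fitness[best_index()])]
    F, CR = params.amplification, params.crossover_rate
    for _ in range(params.generations):
        x_best = population[best_index()]
        for i in range(params.population_size):
            candidates = np.delete(np.arange(params.population_size), i)
            r1, r2, r3, r4, r5 = rng.choice(candidates, size=5, replace=False)
            mutant = (
                population[r1]
                + F * (x_best - population[r1])
                + F * (population[r2] - population[r3])
                + F * (population[r4] - population[r5])
            )
            mutant = np.clip(mutant, -1.0, 1.0)
            cross = rng.random(dim) < CR
            cross[rng.integers(dim)] = True  # guarantee one mutant gene
            trial = np.where(cross, mutant, population[i])
            f_trial, n_trial = evaluate(trial)
            if f_trial < fitness[i] or (
                f_trial == fitness[i] and n_trial < beta_norm[i]
            ):
                population[i] = trial
                fitness[i] = f_trial
                beta_norm[i] = n_trial
        history.append(float(fitness[best_index()]))

    W, b = _unpack_individual(population[best_index()], n_hidden, n_features)
    model = SLFNModel(
        input_weights=W,
        biases=b,
        output_weights=np.zeros((n_hidden, class_labels.size)),
        activation=activation,
        class_labels=class_labels,
        scale_offset=offset,
        scale_factor=factor,
        fitness_history=history,
    )
    H = g(Xs @ W.T + b)
    model.output_weights = _solve_output_weights(H, T)
    return model


# ---------------------------------------------------------------------------
# Linear max-margin vowel gate


@dataclass
class GateModel:
    """One-vs-one linear maximum-margin router over vowel classes."""

    svc: SVC
    class_labels: np.ndarray

    @property
    def pair_weights(self) -> np.ndarray:
        """Stacked w vectors of the pairwise decision functions wT x + b."""
        return self.svc.coef_

    @property
    def pair_biases(self) -> np.ndarray:
        return self.svc.intercept_


def fit_vowel_gate(X: np.ndarray, vowel_labels: Sequence, C: float = 1.0) -> GateModel:
    """Fit the one-vs-one linear gate (majority vote across class pairs)."""
    X = _validate_features(X)
    labels = np.asarray(vowel_labels)
    if np.unique(labels).size < 2:
        raise ValueError("vowel gate needs at least 2 vowel classes")
    svc = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    svc.fit(X, labels)
    return GateModel(svc=svc, class_labels=svc.classes_)


def predict_vowel(gate: GateModel, x: np.ndarray) -> np.ndarray | str:
    """Route feature vector(s) to a vowel label; deterministic."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    pred = gate.svc.predict(np.atleast_2d(x))
    return pred[0] if single else pred


# ---------------------------------------------------------------------------
# Serialization: JSON container with base64 float64 arrays (bit-exact)


def _encode(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype=np.float64)
    return {"shape": list(a.shape), "data": base64.b64encode(a.tobytes()).decode()}


def _decode(d: dict) -> np.ndarray:
    return np.frombuffer(
        base64.b64decode(d["data"]), dtype=np.float64
    ).reshape(d["shape"])


def save_model(model: SLFNModel, path: str | Path) -> None:
    payload = {
        "kind": "slfn",
        "activation": model.activation,
        "class_labels": [str(c) for c in model.class_labels],
        "label_dtype": str(model.class_labels.dtype.kind),
        "input_weights": _encode(model.input_weights),
        "biases": _encode(model.biases),
        "output_weights": _encode(model.output_weights),
        "scale_offset": _encode(model.scale_offset),
        "scale_factor": _encode(model.scale_factor),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SLFNModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "slfn":
        raise ValueError(f"{path} is not a serialized SLFN model")
    labels = np.asarray(payload["class_labels"])
    if payload.get("label_dtype") in ("i", "u"):
        labels = labels.astype(int)
    return SLFNModel(
        input_weights=_decode(payload["input_weights"]),
        biases=_decode(payload["biases"]),
        output_weights=_decode(payload["output_weights"]),
        activation=payload["activation"],
        class_labels=labels,
        scale_offset=_decode(payload["scale_offset"]),
        scale_factor=_decode(payload["scale_factor"]),
    )
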