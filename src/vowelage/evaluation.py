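"""Cross-validated evaluation of the age-estimation pipeline.

Three experiment modes mirror the method's design:

* ``independent`` — one pooled age classifier over all vowels;
* ``vowel`` — six per-vowel age classifiers, test utterances routed to them
  by the linear vowel gate, raw score records collected;
* ``fusion`` — per-speaker fuzzy-or fusion of the routed decisions, with
  local confidence from each score vector and global confidence from
  leave-one-out recall on the training folds.

Folds are speaker-disjoint and age-stratified: all of a child's vowels stay
on the same side of the split, so the classifier never sees a test speaker's
voice during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifiers import (
    SaELMParams,
    elm_fit,
    elm_predict,
    elm_predict_labels,
    fit_vowel_gate,
    predict_vowel,
    saelm_fit,
)
from .fusion import (
    FusionConfig,
    fuzzy_or_fuse,
    global_confidence_loo,
    local_confidence,
    normalize_scores,
)

__all__ = [
    "ConfusionMatrix",
    "ClassifierConfig",
    "ScoreRecord",
    "make_folds",
    "run_vowel_independent",
    "run_vowel_based",
    "run_fusion",
    "accuracy_from_confusion",
    "collapse_confusion",
    "AGE_GROUPS",
]

# the conventional collapsed reporting bands for 7-12 year olds
AGE_GROUPS: tuple[tuple[int, ...], ...] = ((7, 8), (9, 10), (11, 12))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts over true (rows) x predicted (columns) classes."""

    counts: np.ndarray
    class_labels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")
        if counts.shape[0] != len(self.class_labels):
            raise ValueError("labels do not match matrix size")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_labels", tuple(self.class_labels))

    @classmethod
    def from_labels(cls, true, pred, class_labels: Sequence) -> "ConfusionMatrix":
        labels = list(class_labels)
        index = {c: i for i, c in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(true, pred, strict=True):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, class_labels=tuple(labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def overall_accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return 100.0 * float(np.trace(self.counts)) / self.total

    def per_class_accuracy(self) -> np.ndarray:
        """Per-class recall in percent; NaN for classes with no samples."""
        row_sums = self.counts.sum(axis=1)
        diag = np.diag(self.counts).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = 100.0 * diag / row_sums
        return np.where(row_sums > 0, acc, np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_labels), columns=list(self.class_labels)
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_labels != other.class_labels:
            raise ValueError("cannot add confusion matrices over different labels")
        return ConfusionMatrix(self.counts + other.counts, self.class_labels)


def accuracy_from_confusion(cm: ConfusionMatrix) -> tuple[float, np.ndarray]:
    """(overall %, per-class %) — unrounded; display rounding is the caller's."""
    return cm.overall_accuracy(), cm.per_class_accuracy()


def collapse_confusion(
    cm: ConfusionMatrix, grouping: Sequence[Sequence]
) -> ConfusionMatrix:
    """Sum counts within row- and column-groups of a label partition."""
    flat = [lab for group in grouping for lab in group]
    if sorted(map(str, flat)) != sorted(map(str, cm.class_labels)) or len(flat) != len(
        set(flat)
    ):
        raise ValueError("grouping must partition the class labels")
    index = {c: i for i, c in enumerate(cm.class_labels)}
    k = len(grouping)
    counts = np.zeros((k, k), dtype=np.int64)
    for gi, gr in enumerate(grouping):
        for gj, gc in enumerate(grouping):
            rows = [index[r] for r in gr]
            cols = [index[c] for c in gc]
            counts[gi, gj] = cm.counts[np.ix_(rows, cols)].sum()
    labels = tuple("-".join(str(lab) for lab in group) for group in grouping)
    return ConfusionMatrix(counts=counts, class_labels=labels)


# ---------------------------------------------------------------------------
# Folds


def make_folds(frame: pd.DataFrame, k: int = 3, seed: int = 0) -> list[set]:
    """Speaker-disjoint, age-stratified partition into k folds of speaker ids."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    speakers = frame[["speaker_id", "age"]].drop_duplicates("speaker_id")
    counts = speakers["age"].value_counts()
    if (counts < k).any():
        short = counts[counts < k]
        raise ValueError(
            f"each age class needs >= {k} speakers; short classes: "
            f"{dict(short)}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    ids = speakers["speaker_id"].to_numpy()
    ages = speakers["age"].to_numpy()
    return [set(ids[test_idx]) for _, test_idx in skf.split(ids, ages)]


@dataclass(frozen=True)
class ClassifierConfig:
    """Which age classifier to train inside the evaluation loops."""

    method: str = "saelm"  # "saelm" or "elm"
    n_hidden: int = 60
    activation: str = "sigmoid"
    saelm: SaELMParams = field(default_factory=SaELMParams)
    gate_C: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("saelm", "elm"):
            raise ValueError("method must be 'saelm' or 'elm'")


def _feature_matrix(frame: pd.DataFrame) -> np.ndarray:
    cols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    return frame[cols].to_numpy(dtype=np.float64)


def _train_age_classifier(X, y, cfg: ClassifierConfig, seed: int):
    if cfg.method == "elm":
        return elm_fit(X, y, cfg.n_hidden, cfg.activation, seed)
    params = replace(cfg.saelm, n_hidden=cfg.n_hidden, seed=seed)
    return saelm_fit(X, y, params, cfg.activation)


# ---------------------------------------------------------------------------
# Experiment modes


def run_vowel_independent(
    frame: pd.DataFrame,
    folds: Sequence[set],
    cfg: ClassifierConfig | None = None,
    seed: int = 0,
) -> dict:
    """Pooled classifier over all vowels; fold-averaged utterance accuracy."""
    cfg = cfg or ClassifierConfig()
    ages = sorted(frame["age"].unique())
    fold_accuracies = []
    fold_confusions = []
    for fi, test_speakers in enumerate(folds):
        test_mask = frame["speaker_id"].isin(test_speakers)
        train, test = frame[~test_mask], frame[test_mask]
        if len(train) == 0 or len(test) == 0:
            raise ValueError(f"fold {fi} has an empty train or test side")
        model = _train_age_classifier(
            _feature_matrix(train), train["age"].to_numpy(), cfg, seed + fi
        )
        pred = elm_predict_labels(model, _feature_matrix(test))
        cm = ConfusionMatrix.from_labels(test["age"].to_numpy(), pred, ages)
        fold_confusions.append(cm)
        fold_accuracies.append(cm.overall_accuracy())
    pooled = fold_confusions[0]
    for cm in fold_confusions[1:]:
        pooled = pooled + cm
    return {
        "mode": "independent",
        "fold_accuracies": fold_accuracies,
        "mean_accuracy": float(np.mean(fold_accuracies)),
        "fold_confusions": fold_confusions,
        "pooled_confusion": pooled,
    }


@dataclass(frozen=True)
class ScoreRecord:
    """One routed test utterance's raw classifier output."""

    fold: int
    speaker_id: str
    true_age: int
    true_vowel: str
    routed_vowel: str
    raw_scores: np.ndarray
    predicted_age: int


def run_vowel_based(
    frame: pd.DataFrame,
    folds: Sequence[set],
    cfg: ClassifierConfig | None = None,
    seed: int = 0,
    use_gate: bool = True,
    loo_global_confidence: bool = True,
) -> dict:
    """Per-vowel classifiers with gate routing; collects fusion inputs.

    Per-vowel accuracies are computed over utterances grouped by their true
    vowel (routing errors count against the vowel they belong to).  With
    ``use_gate=False`` utterances are routed by their oracle vowel labels.
    Global confidence is estimated per fold by leave-one-out recall of a
    plain-ELM surrogate with the same hidden layer size (a full SaELM refit
    per held-out sample would dominate the runtime without changing the
    winner-take-all structure of the matrix).
    """
    cfg = cfg or ClassifierConfig()
    ages = sorted(frame["age"].unique())
    vowels = sorted(frame["vowel"].unique())
    records: list[ScoreRecord] = []
    gate_hits = gate_total = 0
    delta_by_fold: dict[int, np.ndarray] = {}
    vowel_order_by_fold: dict[int, list] = {}
    for fi, test_speakers in enumerate(folds):
        test_mask = frame["speaker_id"].isin(test_speakers)
        train, test = frame[~test_mask], frame[test_mask]
        missing = set(vowels) - set(train["vowel"].unique())
        if missing:
            raise ValueError(f"fold {fi} training data lacks vowels {missing}")
        models = {}
        feats_by_vowel = {}
        labels_by_vowel = {}
        for v in vowels:
            sub = train[train["vowel"] == v]
            Xv, yv = _feature_matrix(sub), sub["age"].to_numpy()
            models[v] = _train_age_classifier(Xv, yv, cfg, seed + fi)
            feats_by_vowel[v] = Xv
            labels_by_vowel[v] = yv
        if loo_global_confidence:
            factory = lambda X, y, s: _LabelPredictor(
                elm_fit(X, y, cfg.n_hidden, cfg.activation, s)
            )
            delta, order = global_confidence_loo(
                feats_by_vowel, labels_by_vowel, factory, seed + fi
            )
        else:
            delta = np.ones((len(vowels), len(ages)))
            order = vowels
        delta_by_fold[fi] = delta
        vowel_order_by_fold[fi] = list(order)

        gate = (
            fit_vowel_gate(
                _feature_matrix(train), train["vowel"].to_numpy(), cfg.gate_C
            )
            if use_gate
            else None
        )
        X_test = _feature_matrix(test)
        routed = (
            np.asarray(predict_vowel(gate, X_test))
            if use_gate
            else test["vowel"].to_numpy()
        )
        gate_hits += int(np.sum(routed == test["vowel"].to_numpy()))
        gate_total += len(test)
        for row, (_, utt) in zip(range(len(test)), test.iterrows()):
            v = routed[row]
            scores = elm_predict(models[v], X_test[row])[0]
            pred_age = models[v].class_labels[int(np.argmax(scores))]
            records.append(
                ScoreRecord(
                    fold=fi,
                    speaker_id=str(utt["speaker_id"]),
                    true_age=int(utt["age"]),
                    true_vowel=str(utt["vowel"]),
                    routed_vowel=str(v),
                    raw_scores=scores,
                    predicted_age=int(pred_age),
                )
            )
    per_vowel_acc = {}
    for v in vowels:
        sub = [r for r in records if r.true_vowel == v]
        if sub:
            per_vowel_acc[v] = 100.0 * np.mean(
                [r.predicted_age == r.true_age for r in sub]
            )
    return {
        "mode": "vowel",
        "records": records,
        "per_vowel_accuracy": per_vowel_acc,
        "gate_accuracy": 100.0 * gate_hits / max(gate_total, 1),
        "delta_by_fold": delta_by_fold,
        "vowel_order_by_fold": vowel_order_by_fold,
        "age_labels": ages,
    }


class _LabelPredictor:
    """Adapter giving an SLFNModel the predict() surface the LOO loop wants."""

    def __init__(self, model):
        self.model = model

    def predict(self, X):
        return elm_predict_labels(self.model, X)


def run_fusion(
    vowel_results: Mapping,
    config: FusionConfig | None = None,
) -> dict:
    """Fuse each test speaker's routed decisions into one age estimate.

    The fusion unit is the speaker: every routed utterance contributes one
    (membership, local confidence, delta row) triple, and the fuzzy-or
    operator aggregates the m triples (m = utterances of that speaker).
    """
    config = config or FusionConfig()
    records: Sequence[ScoreRecord] = vowel_results["records"]
    if not records:
        raise ValueError("no score records to fuse")
    ages = vowel_results["age_labels"]
    delta_by_fold = vowel_results["delta_by_fold"]
    order_by_fold = vowel_results["vowel_order_by_fold"]

    by_speaker: dict[tuple[int, str], list[ScoreRecord]] = {}
    for r in records:
        by_speaker.setdefault((r.fold, r.speaker_id), []).append(r)

    true_ages, fused_ages = [], []
    fused_records = []
    for (fold, speaker), recs in sorted(by_speaker.items()):
        delta_fold = delta_by_fold[fold]
        order = order_by_fold[fold]
        mu = np.stack([normalize_scores(r.raw_scores) for r in recs])
        w = np.array([local_confidence(r.raw_scores, config.sigma) for r in recs])
        delta = np.stack([delta_fold[order.index(r.routed_vowel)] for r in recs])
        decision = fuzzy_or_fuse(mu, w, delta, config)
        age = ages[decision.winner_index]
        true_ages.append(recs[0].true_age)
        fused_ages.append(age)
        fused_records.append(
            {
                "speaker_id": speaker,
                "fold": fold,
                "true_age": recs[0].true_age,
                "fused_age": int(age),
                "fused_values": decision.fused_values.tolist(),
                "local_confidence": w.tolist(),
                "routed_vowels": [r.routed_vowel for r in recs],
            }
        )
    cm = ConfusionMatrix.from_labels(true_ages, fused_ages, ages)
    return {
        "mode": "fusion",
        "confusion": cm,
        "accuracy": cm.overall_accuracy(),
        "fused_records": fused_records,
    }
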