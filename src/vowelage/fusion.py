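"""Fuzzy decision fusion of a classifier ensemble.

Each classifier's per-class scores for a sample are min-max normalized into a
membership set mu_i^j(x) in [0, 1] — a fuzzy set over the age classes.  Two
reliability signals weight the ensemble:

* local confidence w_i(x): a Gaussian function of how far the classifier's
  top score stands above its runner-up, relative to its score range —
  ``w = exp(-0.5 * (|1 - (S_max1 - S_max2) / (S_max1 - S_min)| / sigma)^2)``;

* global confidence delta_i^j: a binary per-class matrix from leave-one-out
  recall on the training data — for each class, the single classifier with
  the best LOO recall gets delta = 1, all others 0.

The fuzzy-or operator blends a max-like (optimistic) term with an average:

    mu_f^j = gamma * max_i min(w_i mu_i^j, delta_i^j)
           + (1 - gamma) * (1/m) * sum_i w_i mu_i^j delta_i^j

The compensation degree gamma interpolates between pure max (gamma = 1) and
a weighted arithmetic mean (gamma = 0); the winning class is the argmax of
the fused vector, lowest index on ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "MembershipSet",
    "FusionConfig",
    "FusedDecision",
    "normalize_scores",
    "local_confidence",
    "global_confidence_loo",
    "fuzzy_or_fuse",
    "combine_sets",
]


@dataclass(frozen=True)
class MembershipSet:
    """One classifier's normalized per-class memberships for one sample."""

    values: np.ndarray
    classifier_id: int | str = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("membership values must lie in [0, 1]")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class FusionConfig:
    """gamma: compensation degree in [0, 1]; sigma: Gaussian confidence width."""

    gamma: float = 0.6
    sigma: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class FusedDecision:
    fused_values: np.ndarray
    winner_index: int
    winner: object
    classifier_ids: tuple


def normalize_scores(raw_scores: Sequence[float]) -> np.ndarray:
    """Min-max normalize one classifier's score vector into memberships.

    A degenerate all-equal vector maps to the maximally ambiguous uniform
    membership 1/n.
    """
    s = np.asarray(raw_scores, dtype=np.float64)
    if s.size < 2:
        raise ValueError("need at least 2 class scores")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain non-finite values")
    span = s.max() - s.min()
    if span == 0:
        return np.full(s.size, 1.0 / s.size)
    return (s - s.min()) / span


def local_confidence(raw_scores: Sequence[float], sigma: float = 0.05) -> float:
    """Per-sample reliability from the raw (pre-normalization) score vector.

    When the runner-up already sits at the minimum the decision is maximally
    clear and w = 1; a tied top pair gives w = exp(-0.5 / sigma^2), effectively
    zero at the default sigma.  An all-equal vector is treated as that totally
    unreliable limit.
    """
    s = np.asarray(raw_scores, dtype=np.float64)
    if s.size < 2:
        raise ValueError("need at least 2 class scores")
    order = np.sort(s)[::-1]
    s_max1, s_max2, s_min = order[0], order[1], order[-1]
    if s_max1 == s_min:
        ratio = 0.0
    else:
        ratio = (s_max1 - s_max2) / (s_max1 - s_min)
    return float(np.exp(-0.5 * (abs(1.0 - ratio) / sigma) ** 2))


def global_confidence_loo(
    features_by_group: Mapping,
    labels_by_group: Mapping,
    classifier_factory: Callable,
    seed: int = 0,
) -> tuple[np.ndarray, list]:
    """Binary per-class reliability matrix from leave-one-out recall.

    ``classifier_factory(X, labels, seed)`` must return an object with a
    ``predict(X) -> labels`` method.  For each group (vowel) a classifier is
    refit with each training sample held out in turn; per-class recall is the
    fraction of held-out samples of that class predicted correctly.  For each
    class the group with the highest recall gets delta = 1 (ties to the lowest
    group index), all others 0.

    Returns ``(delta, group_ids)`` with delta of shape (n_groups, n_classes)
    over the sorted union of classes.
    """
    group_ids = list(features_by_group)
    if not group_ids:
        raise ValueError("no classifier groups given")
    all_classes = np.unique(
        np.concatenate([np.asarray(labels_by_group[g]) for g in group_ids])
    )
    recalls = np.zeros((len(group_ids), all_classes.size))
    for gi, g in enumerate(group_ids):
        X = np.asarray(features_by_group[g], dtype=np.float64)
        y = np.asarray(labels_by_group[g])
        present = np.unique(y)
        if not np.array_equal(present, all_classes):
            raise ValueError(
                f"group {g!r} lacks classes "
                f"{sorted(set(all_classes.tolist()) - set(present.tolist()))}"
            )
        hits = np.zeros(all_classes.size)
        totals = np.zeros(all_classes.size)
        for k in range(X.shape[0]):
            mask = np.arange(X.shape[0]) != k
            clf = classifier_factory(X[mask], y[mask], seed)
            pred = np.asarray(clf.predict(X[k : k + 1]))[0]
            j = int(np.searchsorted(all_classes, y[k]))
            totals[j] += 1
            hits[j] += pred == y[k]
        recalls[gi] = hits / np.maximum(totals, 1)
    delta = np.zeros_like(recalls)
    winners = np.argmax(recalls, axis=0)  # lowest index on ties
    delta[winners, np.arange(all_classes.size)] = 1.0
    return delta, group_ids


def fuzzy_or_fuse(
    memberships: Sequence[MembershipSet] | np.ndarray,
    local_weights: Sequence[float],
    delta: np.ndarray,
    config: FusionConfig | None = None,
) -> FusedDecision:
    """Fuse m membership sets into one decision with the fuzzy-or operator."""
    config = config or FusionConfig()
    if isinstance(memberships, np.ndarray):
        mu = np.asarray(memberships, dtype=np.float64)
        ids: tuple = tuple(range(mu.shape[0]))
    else:
        mu = np.stack([m.values for m in memberships])
        ids = tuple(m.classifier_id for m in memberships)
    w = np.asarray(local_weights, dtype=np.float64)
    delta = np.asarray(delta, dtype=np.float64)
    m, n = mu.shape
    if w.shape != (m,) or delta.shape != (m, n):
        raise ValueError(
            f"inconsistent shapes: mu {mu.shape}, w {w.shape}, delta {delta.shape}"
        )
    weighted = w[:, None] * mu
    max_term = np.max(np.minimum(weighted, delta), axis=0)
    avg_term = np.mean(weighted * delta, axis=0)
    fused = config.gamma * max_term + (1.0 - config.gamma) * avg_term
    winner = int(np.argmax(fused))
    return FusedDecision(
        fused_values=fused, winner_index=winner, winner=winner, classifier_ids=ids
    )


def combine_sets(
    sets: Sequence[MembershipSet] | Sequence[np.ndarray], mode: str
) -> np.ndarray:
    """Conjunctive (element-wise min / t-norm style) or disjunctive
    (element-wise max / t-conorm style) aggregation of membership sets."""
    if len(sets) == 0:
        raise ValueError("no membership sets to combine")
    values = np.stack(
        [s.values if isinstance(s, MembershipSet) else np.asarray(s) for s in sets]
    )
    if mode == "conjunctive":
        return values.min(axis=0)
    if mode == "disjunctive":
        return values.max(axis=0)
    raise ValueError(f"mode must be 'conjunctive' or 'disjunctive', got {mode!r}")
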