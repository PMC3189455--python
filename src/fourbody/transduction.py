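"""Incremental transduction strategies T1, T2a and T2b.

All three strategies wrap a base binary classifier that exposes continuous
confidence scores ``h`` in the open interval (-1, 1): the sign of ``h`` is
the predicted class and its magnitude the confidence (for a network this is
the tan-sigmoid output unit; for a random forest the fraction ``v`` of trees
voting "active" mapped as ``h = 2v - 1``).

* **T1 (one-shot transduction)** — train on the labeled set L, label the
  whole test set Q, add all of Q to L, and iterate until predicted labels
  stop changing (or an iteration cap is reached).
* **T2a (shrinking test set)** — per iteration only *reliable* examples,
  those with ``|h|`` strictly above a threshold (default 0.8), are annotated
  and moved from Q into L; stops when none qualify or Q empties.
* **T2b (fixed-size test set)** — as T2a, with a secondary pool P that
  replenishes Q back to a fixed working size (default 80) after each shrink;
  stops when no reliable labels are found or both Q and P are exhausted.

Once an example is annotated under T2a/T2b its label is frozen; under T1
labels may flip until convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "BaseClassifier",
    "RandomForestScorer",
    "TransductionConfig",
    "PredictionRecord",
    "IterationLog",
    "TransductionResult",
    "extract_reliable",
    "hard_labels",
    "strategy_t1",
    "strategy_t2a",
    "strategy_t2b",
]


class SingleClassError(ValueError):
    """The labeled set contains only one class and cannot train a classifier."""


class BaseClassifier(Protocol):
    """Contract for base classifiers usable by the strategies."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaseClassifier": ...

    def score_continuous(self, X: np.ndarray) -> np.ndarray:
        """Confidence scores in the open interval (-1, 1)."""
        ...


_EPS = 1e-9


class RandomForestScorer:
    """Random forest with vote-proportion confidence in (-1, 1).

    The continuous score is ``h = 2 v - 1`` where ``v`` is the forest's
    probability for the active (+1) class; with fully grown trees this is
    the fraction of trees voting active.  Scores are clipped infinitesimally
    inside the open interval.
    """

    def __init__(self, n_estimators: int = 100, random_state: int = 0, **kwargs):
        self._clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=random_state, **kwargs
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestScorer":
        self._clf.fit(X, y)
        return self

    def score_continuous(self, X: np.ndarray) -> np.ndarray:
        proba = self._clf.predict_proba(X)
        classes = list(self._clf.classes_)
        v = proba[:, classes.index(1)] if 1 in classes else np.zeros(len(X))
        return np.clip(2.0 * v - 1.0, -1.0 + _EPS, 1.0 - _EPS)


@dataclass(frozen=True)
class TransductionConfig:
    """Knobs shared by the strategies.

    ``reliability_threshold`` is the confidence cut (strict inequality),
    ``q_size`` the fixed working test-set size for T2b, ``max_iter`` the
    iteration cap for T1, and ``seed`` drives every stochastic element
    (currently the T2b pool draws).
    """

    reliability_threshold: float = 0.8
    q_size: int = 80
    max_iter: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.reliability_threshold < 1.0:
            raise ValueError("reliability_threshold must be in (0, 1)")
        if self.q_size < 1 or self.max_iter < 1:
            raise ValueError("q_size and max_iter must be >= 1")


@dataclass(frozen=True)
class PredictionRecord:
    """Final outcome for one test example.

    ``annotated`` is True when the example entered L (T1 always; T2a/T2b
    only if it was reliable at some iteration); never-annotated leftovers
    carry their final-iteration hard label with ``annotated=False``.
    """

    example_id: object
    score: float
    label: int
    iteration: int
    annotated: bool


@dataclass(frozen=True)
class IterationLog:
    iteration: int
    n_labeled: int
    n_test: int
    n_pool: int
    n_reliable: int


@dataclass
class TransductionResult:
    predictions: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)

    def labels(self, ids: Sequence) -> np.ndarray:
        return np.array([self.predictions[i].label for i in ids], dtype=int)


def hard_labels(scores: np.ndarray) -> np.ndarray:
    """Sign of the continuous score; an exact 0 maps to +1."""
    return np.where(scores >= 0.0, 1, -1)


def extract_reliable(scores: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Boolean mask of reliable examples: ``|score|`` strictly above
    ``threshold``."""
    return np.abs(scores) > threshold


def _check_trainable(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise SingleClassError("labeled set must contain both classes")


def strategy_t1(
    X_l: np.ndarray,
    y_l: np.ndarray,
    X_q: np.ndarray,
    classifier: BaseClassifier,
    config: TransductionConfig = TransductionConfig(),
    q_ids: Sequence | None = None,
) -> TransductionResult:
    """One-shot transduction: iterate train / label-all-of-Q to a fixed point."""
    _check_trainable(y_l)
    if len(X_q) == 0:
        raise ValueError("Q must be nonempty")
    ids = list(q_ids) if q_ids is not None else list(range(len(X_q)))
    result = TransductionResult()
    labels_q: np.ndarray | None = None
    scores = np.zeros(len(X_q))
    iteration = 0
    for iteration in range(1, config.max_iter + 1):
        if labels_q is None:
            X_fit, y_fit = X_l, y_l
        else:
            X_fit = np.vstack([X_l, X_q])
            y_fit = np.concatenate([y_l, labels_q])
        classifier.fit(X_fit, y_fit)
        scores = classifier.score_continuous(X_q)
        new_labels = hard_labels(scores)
        result.trace.append(
            IterationLog(iteration, len(y_fit), len(X_q), 0, len(X_q))
        )
        if labels_q is not None and np.array_equal(new_labels, labels_q):
            labels_q = new_labels
            break
        labels_q = new_labels
    assert labels_q is not None
    for i, ex_id in enumerate(ids):
        result.predictions[ex_id] = PredictionRecord(
            ex_id, float(scores[i]), int(labels_q[i]), iteration, True
        )
    return result


def _run_incremental(
    X_l: np.ndarray,
    y_l: np.ndarray,
    X_q: np.ndarray,
    q_ids: list,
    X_p: np.ndarray | None,
    p_ids: list | None,
    classifier: BaseClassifier,
    config: TransductionConfig,
) -> TransductionResult:
    """Shared T2a/T2b loop; T2a is the pool-free case."""
    _check_trainable(y_l)
    result = TransductionResult()
    X_train = X_l.copy()
    y_train = y_l.copy()
    rng = np.random.default_rng(config.seed)
    has_pool = X_p is not None
    pool_X = X_p.copy() if has_pool else np.zeros((0, X_l.shape[1]))
    pool_ids = list(p_ids) if has_pool and p_ids is not None else []
    annotated: set = set()

    iteration = 0
    while len(X_q) > 0:
        iteration += 1
        # L, Q, P must stay pairwise disjoint at every iteration boundary
        assert annotated.isdisjoint(q_ids) and annotated.isdisjoint(pool_ids)
        assert set(q_ids).isdisjoint(pool_ids)
        classifier.fit(X_train, y_train)
        scores = classifier.score_continuous(X_q)
        labels = hard_labels(scores)
        reliable = extract_reliable(scores, config.reliability_threshold)
        n_rel = int(reliable.sum())
        result.trace.append(
            IterationLog(iteration, len(y_train), len(X_q), len(pool_ids), n_rel)
        )
        if n_rel == 0:
            # no reliable labels: report leftovers with final-iteration labels
            for i, ex_id in enumerate(q_ids):
                result.predictions[ex_id] = PredictionRecord(
                    ex_id, float(scores[i]), int(labels[i]), iteration, False
                )
            if len(pool_ids) > 0:  # never-promoted pool examples need labels too
                p_scores = classifier.score_continuous(pool_X)
                p_labels = hard_labels(p_scores)
                for i, ex_id in enumerate(pool_ids):
                    result.predictions[ex_id] = PredictionRecord(
                        ex_id, float(p_scores[i]), int(p_labels[i]), iteration, False
                    )
            break
        for i in np.flatnonzero(reliable):
            ex_id = q_ids[i]
            result.predictions[ex_id] = PredictionRecord(
                ex_id, float(scores[i]), int(labels[i]), iteration, True
            )
            annotated.add(ex_id)
        # L = L ∪ Q1 (with predicted labels), Q = Q − Q1
        X_train = np.vstack([X_train, X_q[reliable]])
        y_train = np.concatenate([y_train, labels[reliable]])
        keep = ~reliable
        X_q = X_q[keep]
        q_ids = [q_ids[i] for i in np.flatnonzero(keep)]
        # T2b: replenish Q from P up to q_size
        if has_pool and len(pool_ids) > 0 and len(q_ids) < config.q_size:
            need = min(config.q_size - len(q_ids), len(pool_ids))
            draw = rng.choice(len(pool_ids), size=need, replace=False)
            mask = np.zeros(len(pool_ids), dtype=bool)
            mask[draw] = True
            X_q = np.vstack([X_q, pool_X[mask]])
            q_ids = q_ids + [pool_ids[i] for i in np.flatnonzero(mask)]
            pool_X = pool_X[~mask]
            pool_ids = [pool_ids[i] for i in np.flatnonzero(~mask)]
    return result


def strategy_t2a(
    X_l: np.ndarray,
    y_l: np.ndarray,
    X_q: np.ndarray,
    classifier: BaseClassifier,
    config: TransductionConfig = TransductionConfig(),
    q_ids: Sequence | None = None,
) -> TransductionResult:
    """Incremental transduction with a shrinking test set (T2a)."""
    ids = list(q_ids) if q_ids is not None else list(range(len(X_q)))
    return _run_incremental(X_l, y_l, X_q, ids, None, None, classifier, config)


def strategy_t2b(
    X_l: np.ndarray,
    y_l: np.ndarray,
    X_q: np.ndarray,
    X_p: np.ndarray,
    classifier: BaseClassifier,
    config: TransductionConfig = TransductionConfig(),
    q_ids: Sequence | None = None,
    p_ids: Sequence | None = None,
) -> TransductionResult:
    """Incremental transduction with a fixed-size test set fed from a pool
    (T2b).  Pool examples are drawn uniformly at random without replacement
    under the config seed."""
    ids_q = list(q_ids) if q_ids is not None else list(range(len(X_q)))
    ids_p = (
        list(p_ids)
        if p_ids is not None
        else list(range(len(X_q), len(X_q) + len(X_p)))
    )
    return _run_incremental(
        X_l, y_l, X_q, ids_q, X_p, ids_p, classifier, config
    )
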