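"""Position-balanced cross-validation and confusion-matrix metrics.

Folds are built by "smart partitions": mutants are grouped by mutated
sequence position and each group is dealt round-robin across folds, so
mutations at every position appear on both the training and the test side
of each split (as evenly as the counts allow).  Per run, confusion matrices
are pooled over folds (micro-average), and summaries are means and standard
deviations over independent runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .transduction import (
    RandomForestScorer,
    TransductionConfig,
    hard_labels,
    strategy_t1,
    strategy_t2a,
    strategy_t2b,
)

__all__ = [
    "FoldAssignment",
    "ConfusionMatrix",
    "RunSummary",
    "smart_partition",
    "metrics",
    "cross_validate",
]

METHODS = ("oneshot", "t1", "t2a", "t2b")


@dataclass
class FoldAssignment:
    """Fold index per mutant (by input list position)."""

    fold_of: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def _position_of(m) -> int:
    return m.position if hasattr(m, "position") else int(m)


def _identity_key(m):
    if hasattr(m, "position") and hasattr(m, "mut_aa"):
        return (m.position, m.mut_aa)
    return None


def smart_partition(mutants: Sequence, k: int, seed: int = 0) -> FoldAssignment:
    """Assign mutants to k folds, balancing each position across folds.

    Mutants sharing a mutated position are shuffled (seeded) and dealt
    round-robin starting at a seed-dependent offset, so per position the
    fold counts differ by at most 1.  ``mutants`` may be
    :class:`~fourbody.mutagenesis.MutantRecord` objects or bare position
    integers; with records, group order is canonicalized by
    ``(position, mut_aa)`` so the assignment depends on mutant identity,
    not input row order.
    """
    n = len(mutants)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of mutants ({n})")
    rng = np.random.default_rng(seed)
    groups: dict[int, list[int]] = {}
    for i, m in enumerate(mutants):
        groups.setdefault(_position_of(m), []).append(i)
    fold_of = np.full(n, -1, dtype=int)
    for pos in sorted(groups):
        idx = groups[pos]
        keys = [_identity_key(mutants[i]) for i in idx]
        if all(key is not None for key in keys):
            idx = [i for _, i in sorted(zip(keys, idx))]
        perm = rng.permutation(len(idx))
        offset = int(rng.integers(k))
        for j, pi in enumerate(perm):
            fold_of[idx[pi]] = (offset + j) % k
    return FoldAssignment(fold_of=fold_of, k=k)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with "active" (+1) as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy %, sensitivity, specificity).

    Accuracy = (TP+TN)/total as a percentage; sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP).  Sensitivity is NaN when TP+FN = 0, and
    specificity NaN when TN+FP = 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else math.nan
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else math.nan
    return acc, sens, spec


@dataclass
class RunSummary:
    mean_accuracy: float
    accuracy_std: float
    mean_sensitivity: float
    mean_specificity: float
    n_runs: int


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    mutants: Sequence,
    k: int = 10,
    method: str = "oneshot",
    n_runs: int = 10,
    seed: int = 0,
    config: TransductionConfig | None = None,
    classifier_factory: Callable[[int], object] | None = None,
) -> tuple[RunSummary, list[ConfusionMatrix]]:
    """k-fold cross-validation with smart partitions, averaged over runs.

    Parameters
    ----------
    X, y
        Feature matrix (one residual profile per row) and +1/-1 labels.
    mutants
        Mutant records (or bare positions) aligned with the rows; drives
        the position-balanced partitioning.
    method
        ``"oneshot"`` (train once, label the test fold), ``"t1"``,
        ``"t2a"`` or ``"t2b"``.  For T2b the test fold is shuffled by the
        run seed; the first ``config.q_size`` examples form the working set
        Q and the remainder the pool P.
    n_runs, seed
        Each run r uses a fresh smart partition seeded with ``seed + r``.
    classifier_factory
        ``callable(run_seed) -> scorer``; defaults to a seeded
        :class:`RandomForestScorer`.

    Returns the across-run summary and the per-run pooled confusion
    matrices.  A run whose training side ever collapses to a single class
    is recorded as failed and excluded from the averages with a warning.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("cross-validation needs fully labeled data (+1/-1)")
    if classifier_factory is None:
        classifier_factory = lambda s: RandomForestScorer(random_state=s)
    base = config or TransductionConfig()

    per_run: list[ConfusionMatrix] = []
    accs, senss, specs = [], [], []
    for r in range(n_runs):
        run_seed = seed + r
        assign = smart_partition(mutants, k, seed=run_seed)
        cm = ConfusionMatrix()
        failed = False
        for fold in range(k):
            tr = assign.train_indices(fold)
            te = assign.test_indices(fold)
            if len(np.unique(y[tr])) < 2:
                warnings.warn(
                    f"run {r}: fold {fold} has single-class training data; "
                    "run excluded"
                )
                failed = True
                break
            fold_seed = int(
                np.random.SeedSequence([seed, r, fold]).generate_state(1)[0]
                % (2**31)
            )
            cfg = TransductionConfig(
                reliability_threshold=base.reliability_threshold,
                q_size=base.q_size,
                max_iter=base.max_iter,
                seed=fold_seed,
            )
            clf = classifier_factory(fold_seed)
            if method == "oneshot":
                clf.fit(X[tr], y[tr])
                y_pred = hard_labels(clf.score_continuous(X[te]))
            elif method == "t1":
                res = strategy_t1(X[tr], y[tr], X[te], clf, cfg, q_ids=list(te))
                y_pred = res.labels(list(te))
            elif method == "t2a":
                res = strategy_t2a(X[tr], y[tr], X[te], clf, cfg, q_ids=list(te))
                y_pred = res.labels(list(te))
            else:  # t2b
                rng = np.random.default_rng(fold_seed)
                order = rng.permutation(len(te))
                q_idx = te[order[: cfg.q_size]]
                p_idx = te[order[cfg.q_size:]]
                res = strategy_t2b(
                    X[tr], y[tr], X[q_idx], X[p_idx], clf, cfg,
                    q_ids=list(q_idx), p_ids=list(p_idx),
                )
                y_pred = res.labels(list(te))
            cm = cm + ConfusionMatrix.from_labels(y[te], y_pred)
        if failed:
            continue
        per_run.append(cm)
        acc, sens, spec = metrics(cm)
        accs.append(acc)
        senss.append(sens)
        specs.append(spec)

    if not per_run:
        raise RuntimeError("every run failed (single-class training folds)")
    std = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    summary = RunSummary(
        mean_accuracy=float(np.mean(accs)),
        accuracy_std=std,
        mean_sensitivity=float(np.nanmean(senss)),
        mean_specificity=float(np.nanmean(specs)),
        n_runs=len(per_run),
    )
    return summary, per_run
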