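"""Transduction strategies: reliability cuts, set dynamics, label recovery."""

import numpy as np
import pytest

from fourbody import (
    RandomForestScorer,
    TransductionConfig,
    extract_reliable,
    hard_labels,
    strategy_t1,
    strategy_t2a,
    strategy_t2b,
)
from fourbody.transduction import SingleClassError


class ScriptedScorer:
    """Deterministic stand-in classifier: score = clip of the first feature."""

    def __init__(self, cap=0.99):
        self.cap = cap

    def fit(self, X, y):
        return self

    def score_continuous(self, X):
        return np.clip(X[:, 0], -self.cap, self.cap)


def make_blobs(n_per_class, dim=5, sep=6.0, seed=0):
    """Two well-separated Gaussian clusters labeled +1 / -1."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(+sep / 2, 1.0, size=(n_per_class, dim))
    neg = rng.normal(-sep / 2, 1.0, size=(n_per_class, dim))
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(n_per_class, int), -np.ones(n_per_class, int)])
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def test_extract_reliable_strict_threshold():
    scores = np.array([0.9, -0.85, 0.3, 0.8, -0.8, 0.0])
    mask = extract_reliable(scores, 0.8)
    assert list(mask) == [True, True, False, False, False, False]
    assert not extract_reliable(np.zeros(4), 0.8).any()


def test_hard_labels_sign_convention():
    assert list(hard_labels(np.array([0.2, -0.3, 0.0]))) == [1, -1, 1]


def test_config_validation():
    with pytest.raises(ValueError):
        TransductionConfig(reliability_threshold=1.0)
    with pytest.raises(ValueError):
        TransductionConfig(q_size=0)
    with pytest.raises(ValueError):
        TransductionConfig(max_iter=0)


def test_single_class_labeled_set_fails():
    X = np.zeros((4, 2))
    with pytest.raises(SingleClassError):
        strategy_t1(X, np.ones(4, int), X, ScriptedScorer())
    with pytest.raises(SingleClassError):
        strategy_t2a(X, np.ones(4, int), X, ScriptedScorer())


def test_t1_recovers_separable_labels_and_converges():
    X_l, y_l = make_blobs(20, seed=1)
    X_q, y_q = make_blobs(30, seed=2)
    res = strategy_t1(X_l, y_l, X_q, RandomForestScorer(random_state=0))
    assert np.array_equal(res.labels(range(len(X_q))), y_q)
    # convergence: labels stable between the last two iterations
    assert len(res.trace) <= 20
    assert all(rec.annotated for rec in res.predictions.values())


def test_t1_max_iter_one_single_pass():
    X_l, y_l = make_blobs(10, seed=3)
    X_q, _ = make_blobs(5, seed=4)
    cfg = TransductionConfig(max_iter=1)
    res = strategy_t1(X_l, y_l, X_q, RandomForestScorer(random_state=0), cfg)
    assert len(res.trace) == 1
    assert len(res.predictions) == len(X_q)


def test_t1_singleton_q():
    X_l, y_l = make_blobs(10, seed=5)
    res = strategy_t1(X_l, y_l, X_l[:1], RandomForestScorer(random_state=0))
    assert len(res.predictions) == 1


def test_t2a_no_reliable_scores_terminates_without_augmentation():
    """All scores at or below the threshold: one iteration, no annotation."""
    X_l = np.array([[0.5], [-0.5], [0.4], [-0.4]])
    y_l = np.array([1, -1, 1, -1])
    X_q = np.array([[0.8], [-0.7], [0.2]])
    res = strategy_t2a(X_l, y_l, X_q, ScriptedScorer(), TransductionConfig())
    assert len(res.trace) == 1
    assert res.trace[0].n_reliable == 0
    assert all(not rec.annotated for rec in res.predictions.values())
    assert len(res.predictions) == 3  # leftovers still get hard labels


def test_t2a_empties_q_on_separable_data():
    X_l, y_l = make_blobs(25, seed=6)
    X_q, y_q = make_blobs(40, seed=7)
    res = strategy_t2a(X_l, y_l, X_q, RandomForestScorer(random_state=0))
    assert np.array_equal(res.labels(range(len(X_q))), y_q)
    assert all(rec.annotated for rec in res.predictions.values())
    # |Q| strictly decreases on every continuing iteration
    sizes = [log.n_test for log in res.trace]
    assert all(b < a for a, b in zip(sizes, sizes[1:]))
    assert res.trace[-1].n_test - res.trace[-1].n_reliable == 0


def test_t2a_labeled_set_growth_matches_annotations():
    X_l, y_l = make_blobs(25, seed=8)
    X_q, _ = make_blobs(40, seed=9)
    res = strategy_t2a(X_l, y_l, X_q, RandomForestScorer(random_state=0))
    for a, b in zip(res.trace, res.trace[1:]):
        assert b.n_labeled == a.n_labeled + a.n_reliable
        assert b.n_test == a.n_test - a.n_reliable


def test_each_example_predicted_exactly_once():
    X_l, y_l = make_blobs(20, seed=10)
    X_q, _ = make_blobs(50, seed=11)
    res = strategy_t2a(X_l, y_l, X_q, RandomForestScorer(random_state=0))
    assert sorted(res.predictions) == list(range(len(X_q)))


def test_t2b_refills_q_to_fixed_size():
    """While the pool is nonempty, |Q| is back at q_size at every iteration
    boundary after the first."""
    X_l, y_l = make_blobs(25, seed=12)
    X_q, _ = make_blobs(40, seed=13)   # 80 examples
    X_p, _ = make_blobs(100, seed=14)  # 200-example pool
    cfg = TransductionConfig(q_size=80, seed=5)
    res = strategy_t2b(X_l, y_l, X_q, X_p, RandomForestScorer(random_state=0), cfg)
    for log in res.trace[1:]:
        if log.n_pool > 0:
            assert log.n_test == 80
    assert len(res.predictions) == 280


def test_t2b_annotates_pool_correctly_on_separable_data():
    X_l, y_l = make_blobs(25, seed=15)
    X_q, y_q = make_blobs(40, seed=16)
    X_p, y_p = make_blobs(100, seed=17)
    cfg = TransductionConfig(q_size=80, seed=5)
    res = strategy_t2b(X_l, y_l, X_q, X_p, RandomForestScorer(random_state=0), cfg)
    truth = np.concatenate([y_q, y_p])
    assert np.array_equal(res.labels(range(280)), truth)


def test_t2b_with_empty_pool_reduces_to_t2a():
    X_l, y_l = make_blobs(20, seed=18)
    X_q, _ = make_blobs(30, seed=19)
    empty = np.zeros((0, X_q.shape[1]))
    cfg = TransductionConfig(seed=7)
    r_a = strategy_t2a(X_l, y_l, X_q, RandomForestScorer(random_state=0), cfg)
    r_b = strategy_t2b(X_l, y_l, X_q, empty, RandomForestScorer(random_state=0), cfg)
    assert {i: (p.score, p.label) for i, p in r_a.predictions.items()} == {
        i: (p.score, p.label) for i, p in r_b.predictions.items()
    }


def test_determinism_same_seed_same_result():
    X_l, y_l = make_blobs(20, seed=20)
    X_q, _ = make_blobs(30, seed=21)
    X_p, _ = make_blobs(50, seed=22)
    cfg = TransductionConfig(q_size=40, seed=3)
    runs = [
        strategy_t2b(X_l, y_l, X_q, X_p, RandomForestScorer(random_state=1), cfg)
        for _ in range(2)
    ]
    assert [
        (i, p.score, p.label, p.iteration) for i, p in sorted(runs[0].predictions.items())
    ] == [
        (i, p.score, p.label, p.iteration) for i, p in sorted(runs[1].predictions.items())
    ]
    assert runs[0].trace == runs[1].trace


def test_rf_scorer_contract():
    """Scores live in the open interval (-1, 1)."""
    X, y = make_blobs(30, seed=23)
    clf = RandomForestScorer(n_estimators=50, random_state=0).fit(X, y)
    s = clf.score_continuous(X)
    assert np.all(np.abs(s) < 1.0)
    assert np.array_equal(hard_labels(s), y)
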