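"""Evaluation metrics against hand values and O(n^2) brute-force oracles."""

import numpy as np
import pytest

from rbpsvm.exceptions import MetricError
from rbpsvm.metrics import (
    ConfusionCounts,
    confusion,
    evaluation_report,
    optimal_cutoff_pr,
    pr,
    roc,
    scalar_metrics,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def auroc_pair_counting(scores, labels):
    """Mann-Whitney pair statistic, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def aupr_exhaustive_sweep(scores, labels):
    """Step-rule AP over distinct cutoffs, computed by explicit counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    area, prev_recall = 0.0, 0.0
    for cut in sorted(set(scores.tolist()), reverse=True):
        called = scores >= cut
        tp = int(np.sum(called & (labels == 1)))
        fp = int(np.sum(called & (labels == 0)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def best_f1_brute_force(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best = (np.inf, -1.0)
    for cut in sorted(set(scores.tolist()), reverse=True):
        called = scores >= cut
        tp = int(np.sum(called & (labels == 1)))
        fp = int(np.sum(called & (labels == 0)))
        fn = int(np.sum(~called & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best[1]:
            best = (cut, f1)
    return best


def _random_instance(rng, allow_ties=True):
    n = int(rng.integers(10, 200))
    labels = rng.integers(0, 2, size=n)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[0] = 0
    if allow_ties:
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
    else:
        scores = rng.permutation(n).astype(float)
    return scores, labels


# ---------------------------------------------------------------------------
# frozen hand examples
# ---------------------------------------------------------------------------

def test_confusion_hand_examples():
    c = confusion([0.9, 0.2], [1, 0], 0.5)
    assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)
    c = confusion([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0], 0.5)
    assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)
    c = confusion([0.9, 0.4], [1, 0], 2.0)
    assert c.tp == 0 and c.fp == 0


def test_scalar_metrics_hand_computation():
    m = scalar_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
    assert m["sensitivity"] == pytest.approx(0.6)
    assert m["specificity"] == pytest.approx(0.8)
    assert m["bacc"] == pytest.approx(0.7)
    assert m["mcc"] == pytest.approx(10 / np.sqrt(600))
    assert m["flags"] == []


def test_scalar_metrics_perfect_and_degenerate():
    perfect = scalar_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
    assert all(perfect[k] == 1.0 for k in ("sensitivity", "specificity", "precision", "bacc", "mcc"))
    # all-positive predictions on balanced data: MCC denominator is zero
    degenerate = scalar_metrics(ConfusionCounts(tp=5, fp=5, tn=0, fn=0))
    assert degenerate["mcc"] == 0.0 and "mcc" in degenerate["flags"]


def test_auroc_hand_values():
    assert roc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]).area == pytest.approx(1.0)
    assert roc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]).area == pytest.approx(0.75)


def test_aupr_trivial_cases():
    assert pr([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]).area == pytest.approx(1.0)
    # single positive ranked first of 10
    scores = np.linspace(1.0, 0.1, 10)
    labels = [1] + [0] * 9
    assert pr(scores, labels).area == pytest.approx(1.0)


def test_optimal_cutoff_hand_example():
    cutoff, f1 = optimal_cutoff_pr([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
    assert cutoff == pytest.approx(0.7)
    assert f1 == pytest.approx(0.8)


def test_optimal_cutoff_perfect_separation():
    cutoff, f1 = optimal_cutoff_pr([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
    assert cutoff == pytest.approx(0.8)  # lowest positive score
    assert f1 == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# oracle equivalence and properties
# ---------------------------------------------------------------------------

def test_auroc_matches_pair_counting_oracle(rng):
    for _ in range(50):
        scores, labels = _random_instance(rng)
        assert roc(scores, labels).area == pytest.approx(
            auroc_pair_counting(scores, labels), abs=1e-12
        )


def test_aupr_matches_exhaustive_sweep_oracle(rng):
    for _ in range(50):
        scores, labels = _random_instance(rng)
        assert pr(scores, labels).area == pytest.approx(
            aupr_exhaustive_sweep(scores, labels), abs=1e-12
        )


def test_optimal_cutoff_matches_brute_force(rng):
    for _ in range(50):
        scores, labels = _random_instance(rng)
        cutoff, f1 = optimal_cutoff_pr(scores, labels)
        oracle_cutoff, oracle_f1 = best_f1_brute_force(scores, labels)
        assert f1 == pytest.approx(oracle_f1, abs=1e-12)
        assert cutoff == pytest.approx(oracle_cutoff, abs=1e-12)


def test_auroc_monotone_transform_invariance(rng):
    scores, labels = _random_instance(rng)
    base = roc(scores, labels).area
    assert roc(np.exp(scores), labels).area == pytest.approx(base, abs=1e-12)
    assert roc(3 * scores + 7, labels).area == pytest.approx(base, abs=1e-12)


def test_auroc_score_negation_complement(rng):
    scores, labels = _random_instance(rng, allow_ties=False)
    a = roc(scores, labels).area
    b = roc(-scores, labels).area
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_aupr_converges_to_prevalence_for_random_scores(rng):
    n, prevalence = 10000, 0.2
    labels = (rng.random(n) < prevalence).astype(int)
    scores = rng.random(n)
    assert pr(scores, labels).area == pytest.approx(labels.mean(), abs=0.03)


def test_roc_points_monotone(rng):
    scores, labels = _random_instance(rng)
    curve = roc(scores, labels)
    xs = [p[0] for p in curve.points]
    ys = [p[1] for p in curve.points]
    assert all(b >= a for a, b in zip(xs, xs[1:]))
    assert all(b >= a for a, b in zip(ys, ys[1:]))


def test_metric_errors():
    with pytest.raises(MetricError):
        confusion([0.5], [1, 0], 0.0)
    with pytest.raises(MetricError):
        roc([0.5, 0.6], [1, 1])
    with pytest.raises(MetricError):
        pr([0.5, 0.6], [0, 0])


def test_evaluation_report_consistency(rng):
    scores, labels = _random_instance(rng)
    report = evaluation_report(scores, labels)
    assert report["auroc"] == pytest.approx(roc(scores, labels).area)
    assert report["cutoff"] == optimal_cutoff_pr(scores, labels)[0]
    assert report["counts"].total == len(labels)
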