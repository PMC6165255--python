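"""Confusion metrics, t-test, majority vote, and recognition rate."""

import numpy as np
import pytest

from histosift.evaluate import (
    PatientRecord,
    confusion_and_weighted_metrics,
    majority_vote,
    paired_ttest,
    recognition_rate,
)


def brute_force_weighted_metrics(actual, predicted):
    """Independent oracle: metrics from first principles, no library calls."""
    classes = sorted(set(actual) | set(predicted))
    n = len(actual)
    wp = wr = wf = 0.0
    per = {}
    for c in classes:
        tp = sum(1 for a, p in zip(actual, predicted) if a == c and p == c)
        fp = sum(1 for a, p in zip(actual, predicted) if a != c and p == c)
        fn = sum(1 for a, p in zip(actual, predicted) if a == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        support = tp + fn
        per[c] = (prec, rec, f, support)
        wp += prec * support / n
        wr += rec * support / n
        wf += f * support / n
    return per, wp, wr, wf


def test_perfect_predictions():
    rep = confusion_and_weighted_metrics(["a", "b", "c"] * 4, ["a", "b", "c"] * 4)
    assert rep.weighted_precision == rep.weighted_recall == rep.weighted_f_measure == 1.0
    assert (rep.per_class[["precision", "recall", "f_measure"]] == 1.0).all().all()
    assert np.trace(rep.confusion.counts) == 12


def test_two_class_hand_computed_values():
    """Confusion rows (2,0)/(1,1): weighted P 0.8333, R 0.75, F 0.7333."""
    actual = ["x", "x", "y", "y"]
    predicted = ["x", "x", "x", "y"]
    rep = confusion_and_weighted_metrics(actual, predicted)
    np.testing.assert_array_equal(rep.confusion.counts, [[2, 0], [1, 1]])
    assert rep.weighted_precision == pytest.approx(0.8333, abs=1e-4)
    assert rep.weighted_recall == pytest.approx(0.75, abs=1e-12)
    assert rep.weighted_f_measure == pytest.approx(0.7333, abs=1e-4)


def test_never_predicted_class_gets_zero_precision(caplog):
    with caplog.at_level("WARNING", logger="histosift.evaluate"):
        rep = confusion_and_weighted_metrics(["a", "a", "b"], ["a", "a", "a"])
    assert rep.per_class.loc["b", "precision"] == 0.0
    assert any("never predicted" in r.message for r in caplog.records)


def test_label_outside_class_set_errors():
    with pytest.raises(ValueError, match="outside declared"):
        confusion_and_weighted_metrics(["a", "b"], ["a", "q"], classes=["a", "b"])


def test_metrics_match_brute_force_oracle():
    rng = np.random.default_rng(99)
    labels = np.array(["u", "pd", "d", "gn", "gnb"])
    for _ in range(100):
        n = rng.integers(5, 60)
        actual = labels[rng.integers(0, 5, n)]
        predicted = labels[rng.integers(0, 5, n)]
        rep = confusion_and_weighted_metrics(actual, predicted)
        per, wp, wr, wf = brute_force_weighted_metrics(list(actual), list(predicted))
        assert rep.weighted_precision == pytest.approx(wp, abs=1e-9)
        assert rep.weighted_recall == pytest.approx(wr, abs=1e-9)
        assert rep.weighted_f_measure == pytest.approx(wf, abs=1e-9)
        # weighted recall equals overall accuracy
        assert rep.weighted_recall == pytest.approx(rep.accuracy, abs=1e-12)
        # report consistency: weighted metric is the support-weighted mean
        sup = rep.per_class["support"].to_numpy()
        assert rep.weighted_f_measure == pytest.approx(
            float((rep.per_class["f_measure"] * sup).sum() / sup.sum()), abs=1e-12
        )


def test_paired_ttest_basics():
    same = [0.8, 0.82, 0.79, 0.81]
    t, p, sig = paired_ttest(same, same)
    assert p == 1.0 and not sig
    rng = np.random.default_rng(0)
    base = 0.8 + rng.normal(0, 0.005, 10)
    t, p, sig = paired_ttest(base + 0.1, base + rng.normal(0, 0.001, 10))
    assert sig and p < 0.05
    with pytest.raises(ValueError):
        paired_ttest([0.5], [0.6])


def test_paired_ttest_zero_variance_shift(caplog):
    with caplog.at_level("WARNING", logger="histosift.evaluate"):
        t, p, sig = paired_ttest([0.9] * 5, [0.8] * 5)
    assert p == 0.0 and sig
    assert any("zero variance" in r.message for r in caplog.records)


def test_majority_vote_unanimous_and_plurality():
    label, count = majority_vote(["ganglioneuroma"] * 10)
    assert (label, count) == ("ganglioneuroma", 10)
    votes = ["poorly-differentiated"] * 4 + ["differentiating"] * 6
    label, count = majority_vote(votes)
    assert (label, count) == ("differentiating", 6)


def test_majority_vote_tie_breaks():
    votes = ["a"] * 5 + ["b"] * 5
    scores = [{"a": 0.2, "b": 0.1}] * 10
    assert majority_vote(votes, scores) == ("a", 5)
    scores = [{"a": 0.1, "b": 0.4}] * 10
    assert majority_vote(votes, scores) == ("b", 5)
    # no scores: lexicographic
    assert majority_vote(votes) == ("a", 5)
    with pytest.raises(ValueError):
        majority_vote([])


def test_recognition_rate_hand_values():
    assert recognition_rate([PatientRecord("p1", 4, 4)]) == 1.0
    recs = [PatientRecord("p1", 4, 3), PatientRecord("p2", 2, 1)]
    assert recognition_rate(recs) == pytest.approx((0.75 + 0.5) / 2)
    # duplication and ordering invariance
    assert recognition_rate(recs + recs) == pytest.approx(0.625)
    assert recognition_rate(recs[::-1]) == pytest.approx(0.625)


def test_patient_record_validation():
    with pytest.raises(ValueError):
        PatientRecord("p", 0, 0)
    with pytest.raises(ValueError):
        PatientRecord("p", 3, 4)
    with pytest.raises(ValueError):
        recognition_rate([])
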