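"""Tests for confusion tallies, the metric suite, OVR AUC, and the ANOVA
comparison."""

import numpy as np
import pytest

from snakeswarm.metrics import (
    compare_with_anova,
    confusion_tally,
    metrics_from_tally,
    roc_auc_ovr,
)


def brute_force_auc(pos_scores, neg_scores):
    """Exhaustive pair-counting oracle with half credit for ties."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos_scores for n in neg_scores
    )
    return wins / (len(pos_scores) * len(neg_scores))


class TestConfusionTally:
    def test_perfect_predictions(self):
        t = confusion_tally(["a", "b", "a"], ["a", "b", "a"])
        assert np.all(t.fp == 0) and np.all(t.fn == 0)

    def test_binary_enumeration(self):
        t = confusion_tally(["+", "+", "-"], ["+", "-", "-"], classes=["-", "+"])
        i = t.classes.index("+")
        assert (t.tp[i], t.fn[i], t.tn[i], t.fp[i]) == (1, 1, 1, 0)

    def test_supports_conserve_n(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 4, 60)
        p = rng.integers(0, 4, 60)
        t = confusion_tally(y, p, classes=[0, 1, 2, 3])
        assert t.support.sum() == 60

    def test_unknown_prediction_rejected(self):
        with pytest.raises(ValueError, match="label-mismatch"):
            confusion_tally([0, 1], [0, 9], classes=[0, 1])


class TestMetricsFromTally:
    def test_hand_computed_fixture(self):
        from snakeswarm.metrics import ConfusionTally

        tally = ConfusionTally(
            classes=["pos"],
            tp=np.array([50]), fp=np.array([10]), fn=np.array([5]), tn=np.array([35]),
        )
        m = metrics_from_tally(tally).per_class["pos"]
        assert m["precision"] == pytest.approx(0.83333, abs=1e-5)
        assert m["recall"] == pytest.approx(0.90909, abs=1e-5)
        assert m["accuracy"] == pytest.approx(0.85, abs=1e-5)
        assert m["f1"] == pytest.approx(0.86957, abs=1e-5)
        assert m["specificity"] == pytest.approx(0.77778, abs=1e-5)

    def test_error_rate_complements_accuracy(self):
        y = [0, 0, 1, 1, 2]
        p = [0, 1, 1, 1, 2]
        rep = metrics_from_tally(confusion_tally(y, p, classes=[0, 1, 2]))
        assert rep.error_rate == pytest.approx(1 - rep.accuracy, abs=1e-12)
        assert rep.accuracy == pytest.approx(np.mean(np.array(y) == np.array(p)))

    def test_all_correct_gives_ones(self):
        rep = metrics_from_tally(confusion_tally([0, 1, 0], [0, 1, 0], classes=[0, 1]))
        for cls in (0, 1):
            assert all(
                rep.per_class[cls][m] == 1.0
                for m in ("precision", "recall", "f1", "specificity", "accuracy")
            )

    def test_zero_denominator_flagged_not_nan(self):
        # class 2 never predicted nor present -> precision/recall denominators 0
        rep = metrics_from_tally(confusion_tally([0, 0, 1], [0, 0, 1], classes=[0, 1, 2]))
        assert rep.per_class[2]["precision"] == 0.0
        assert any(f.startswith("zero-denominator") for f in rep.flags)

    def test_binary_agrees_with_two_class_formulas(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        rep = metrics_from_tally(confusion_tally(y, p, classes=[0, 1]))
        tp = int(np.sum((y == 1) & (p == 1)))
        fp = int(np.sum((y == 0) & (p == 1)))
        fn = int(np.sum((y == 1) & (p == 0)))
        assert rep.per_class[1]["precision"] == pytest.approx(tp / (tp + fp))
        assert rep.per_class[1]["recall"] == pytest.approx(tp / (tp + fn))


class TestRocAuc:
    def test_perfect_ordering(self):
        scores = np.array([[0.9], [0.8], [0.2], [0.1]])
        auc = roc_auc_ovr([1, 1, 0, 0], np.hstack([1 - scores, scores]), classes=[0, 1])
        assert auc[1]["auc"] == 1.0

    def test_constant_scores_half(self):
        scores = np.ones((6, 2)) * 0.5
        auc = roc_auc_ovr([0, 0, 0, 1, 1, 1], scores, classes=[0, 1])
        assert auc[0]["auc"] == 0.5 and auc[1]["auc"] == 0.5

    def test_hand_worked_four_samples(self):
        # class-+ scores [0.9, 0.4] vs rest [0.8, 0.1]: 3 wins + 1 loss of 4 pairs
        y = ["+", "+", "-", "-"]
        s = np.array([[0.1, 0.9], [0.6, 0.4], [0.2, 0.8], [0.9, 0.1]])
        auc = roc_auc_ovr(y, s, classes=["-", "+"])
        assert auc["+"]["auc"] == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(6, 50)
            k = rng.integers(2, 5)
            y = rng.integers(0, k, n)
            scores = np.round(rng.random((n, k)), 1)  # coarse grid forces ties
            result = roc_auc_ovr(y, scores, classes=list(range(k)))
            for cls in range(k):
                pos = scores[y == cls, cls]
                neg = scores[y != cls, cls]
                if len(pos) == 0 or len(neg) == 0:
                    assert result[cls]["auc"] is None
                else:
                    assert result[cls]["auc"] == pytest.approx(
                        brute_force_auc(pos, neg), abs=1e-12
                    )

    def test_absent_class_flagged(self):
        auc = roc_auc_ovr([0, 0], np.ones((2, 2)), classes=[0, 1])
        assert auc[1]["auc"] is None and auc[1]["flag"] == "class-absent"


class TestAnova:
    def test_identical_groups(self):
        f, p, means = compare_with_anova([1, 2, 3], [1, 2, 3])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)
        assert means == (2.0, 2.0)

    def test_hand_worked_f_and_p(self):
        f, p, means = compare_with_anova([1, 2], [3, 4])
        assert f == pytest.approx(8.0, abs=1e-10)
        assert p == pytest.approx(0.1056, abs=1e-3)
        assert means == (1.5, 3.5)

    def test_shift_invariance(self):
        f1, _, _ = compare_with_anova([1, 2], [3, 4])
        f2, _, _ = compare_with_anova([101, 102], [103, 104])
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_zero_variance_unequal_means(self):
        f, p, _ = compare_with_anova([1, 1], [2, 2])
        assert np.isinf(f) and p == 0.0

    def test_short_group_rejected(self):
        with pytest.raises(ValueError):
            compare_with_anova([1], [2, 3])
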