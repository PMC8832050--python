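"""Confusion-matrix arithmetic and per-class metric definitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgnet import (ConfusionMatrix, LabelTaxonomy, average_over_folds,
                    confusion, metrics_from_confusion, mislocalization_rate)
from ecgnet.metrics import ClassMetrics, MetricsReport, percent


def _report_from_counts(counts, names):
    return metrics_from_confusion(ConfusionMatrix(np.asarray(counts), names))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        tax = LabelTaxonomy(("a", "b", "c"))
        y = np.array([0, 1, 2, 2, 1, 0])
        cm = confusion(y, y, tax)
        assert cm.trace == 6 and cm.total == 6
        assert np.all(cm.counts == np.diag([2, 2, 2]))

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import confusion_matrix as sk_confusion

        rng = np.random.default_rng(0)
        tax = LabelTaxonomy(("x", "y", "z"))
        t = rng.integers(0, 3, 50)
        p = rng.integers(0, 3, 50)
        cm = confusion(t, p, tax)
        np.testing.assert_array_equal(cm.counts, sk_confusion(t, p, labels=[0, 1, 2]))

    def test_label_outside_taxonomy_is_named(self):
        tax = LabelTaxonomy(("a", "b"))
        with pytest.raises(ValueError, match=r"\[5\]"):
            confusion(np.array([0, 5]), np.array([0, 1]), tax)

    def test_mismatched_lengths_rejected(self):
        tax = LabelTaxonomy(("a", "b"))
        with pytest.raises(ValueError, match="equal length"):
            confusion(np.array([0]), np.array([0, 1]), tax)


class TestMetricsFromConfusion:
    def test_two_class_hand_arithmetic(self):
        """[[90,10],[5,95]]: second-class SEN=95/100, PRE=95/105."""
        rep = _report_from_counts([[90, 10], [5, 95]], ("neg", "pos"))
        m = rep.per_class["pos"]
        assert m.sen == pytest.approx(95 / 100)
        assert m.pre == pytest.approx(95 / 105)
        assert m.spe == pytest.approx(90 / 100)
        assert m.acc == pytest.approx(185 / 200)
        sen, pre = 95 / 100, 95 / 105
        assert m.f1 == pytest.approx(2 * sen * pre / (sen + pre))

    def test_identity_matrix_gives_all_hundreds(self):
        rep = _report_from_counts(np.diag(np.arange(1, 12)),
                                  tuple(f"c{i}" for i in range(11)))
        for m in rep.per_class.values():
            assert m.as_percent() == {"ACC": 100.0, "PRE": 100.0, "SPE": 100.0,
                                      "SEN": 100.0, "F1": 100.0}

    def test_absent_class_metrics_are_none_not_zero(self):
        rep = _report_from_counts([[10, 0, 0], [0, 5, 0], [0, 0, 0]],
                                  ("a", "b", "absent"))
        m = rep.per_class["absent"]
        assert m.sen is None and m.f1 is None
        assert m.spe == pytest.approx(1.0)

    def test_binary_mirror_symmetry(self):
        """For K=2 the classes exchange SEN and SPE (TP and TN swap roles)."""
        rep = _report_from_counts([[80, 20], [10, 90]], ("n", "p"))
        assert rep.per_class["n"].sen == pytest.approx(rep.per_class["p"].spe)
        assert rep.per_class["p"].sen == pytest.approx(rep.per_class["n"].spe)
        assert rep.per_class["n"].acc == pytest.approx(rep.per_class["p"].acc)

    def test_macro_invariant_to_class_permutation(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 40, (4, 4))
        names = ("a", "b", "c", "d")
        rep = _report_from_counts(counts, names)
        perm = [2, 0, 3, 1]
        rep_p = _report_from_counts(counts[np.ix_(perm, perm)],
                                    tuple(names[i] for i in perm))
        for metric in ("acc", "pre", "spe", "sen", "f1"):
            assert getattr(rep.macro, metric) == pytest.approx(
                getattr(rep_p.macro, metric))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_agrees_with_per_beat_tally_oracle(self, seed):
        """One-vs-rest metrics equal a brute-force per-beat tally on random
        confusion matrices."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        counts = rng.integers(0, 12, (k, k))
        if counts.sum() == 0:
            counts[0, 0] = 1
        names = tuple(f"c{i}" for i in range(k))
        rep = _report_from_counts(counts, names)
        # reconstruct the beat list and tally TP/FP/TN/FN directly
        beats = [(i, j) for i in range(k) for j in range(k)
                 for _ in range(counts[i, j])]
        for c in range(k):
            tp = sum(1 for t, p in beats if t == c and p == c)
            fn = sum(1 for t, p in beats if t == c and p != c)
            fp = sum(1 for t, p in beats if t != c and p == c)
            tn = sum(1 for t, p in beats if t != c and p != c)
            m = rep.per_class[names[c]]
            assert m.acc == pytest.approx((tp + tn) / len(beats))
            for value, num, den in ((m.sen, tp, tp + fn), (m.pre, tp, tp + fp),
                                    (m.spe, tn, tn + fp)):
                if den == 0:
                    assert value is None
                else:
                    assert value == pytest.approx(num / den)


class TestMislocalization:
    def test_diagonal_matrix_rate_zero(self):
        cm = ConfusionMatrix(np.diag([5, 6, 7]), ("H", "A", "I"))
        rate, wrong, diseased = mislocalization_rate(cm, "H")
        assert rate == 0.0 and wrong == 0 and diseased == 13

    def test_counting_matches_brute_force(self):
        counts = np.array([[9, 1, 0], [2, 6, 3], [1, 2, 8]])
        cm = ConfusionMatrix(counts, ("H", "A", "I"))
        rate, wrong, diseased = mislocalization_rate(cm, "H")
        # brute force: true != H, predicted another non-H class
        beats = [(i, j) for i in range(3) for j in range(3)
                 for _ in range(counts[i, j])]
        expect = sum(1 for t, p in beats if t != 0 and p != 0 and t != p)
        denom = sum(1 for t, _ in beats if t != 0)
        assert wrong == expect and diseased == denom
        assert rate == pytest.approx(expect / denom)

    def test_missing_healthy_class_rejected(self):
        cm = ConfusionMatrix(np.diag([5, 6]), ("A", "I"))
        with pytest.raises(ValueError, match="'H'"):
            mislocalization_rate(cm, "H")


class TestFoldAveraging:
    def test_identical_reports_average_to_themselves(self):
        rep = _report_from_counts([[10, 2], [1, 9]], ("n", "p"))
        avg = average_over_folds([rep, rep, rep])
        for name in ("n", "p"):
            for metric in ("acc", "pre", "spe", "sen", "f1"):
                assert getattr(avg.per_class[name], metric) == pytest.approx(
                    getattr(rep.per_class[name], metric))

    def test_hand_arithmetic_on_two_reports(self):
        def mk(acc, sen):
            m = ClassMetrics(acc=acc, sen=sen)
            return MetricsReport(("c",), {"c": m}, m, overall_accuracy=acc,
                                 support={"c": 10})
        avg = average_over_folds([mk(0.9, 0.8), mk(0.7, 0.6)])
        assert avg.per_class["c"].acc == pytest.approx(0.8)
        assert avg.per_class["c"].sen == pytest.approx(0.7)
        assert avg.support["c"] == 20

    def test_taxonomy_mismatch_rejected(self):
        a = _report_from_counts([[1, 0], [0, 1]], ("x", "y"))
        b = _report_from_counts([[1, 0], [0, 1]], ("x", "z"))
        with pytest.raises(ValueError, match="mismatch"):
            average_over_folds([a, b])


class TestPresentation:
    def test_percent_rounds_half_up_at_two_decimals(self):
        assert percent(0.99975) == 99.98
        assert percent(0.999849) == 99.98
        assert percent(0.5) == 50.0
        assert percent(None) is None

    def test_csv_layout_has_class_rows_and_average(self, tmp_path):
        rep = _report_from_counts([[10, 2], [1, 9]], ("HC", "MI"))
        path = rep.to_csv(tmp_path / "t.csv")
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("Category")
        assert [ln.split(",")[0] for ln in lines[1:]] == ["HC", "MI", "Average"]
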