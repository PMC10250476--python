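import numpy as np
import pytest

from ethopose.classify import ClassifierConfig
from ethopose.evaluate import (
    confusion,
    cv5_nonshuffled,
    fold_boundaries,
    learning_curve,
    precision_recall_f1,
    validation_curve,
    weighted_f1,
)
from ethopose.features import WindowDataset, WindowSpec
from oracle_metrics import (
    confusion_tally,
    precision_recall_f1_tally,
    weighted_f1_tally,
)


@pytest.fixture(scope="module")
def blocked_dataset():
    """Three separable classes interleaved in temporal blocks."""
    rng = np.random.default_rng(42)
    centers = {"a": (0.0, 0.0), "b": (6.0, 0.0), "c": (0.0, 6.0)}
    vectors, labels = [], []
    for _ in range(20):  # 20 rounds x 3 blocks of 10 -> 600 windows
        for cls, (cx, cy) in centers.items():
            vectors.append(rng.normal((cx, cy), 1.0, size=(10, 2)))
            labels.extend([cls] * 10)
    vectors = np.vstack(vectors).astype(np.float32)
    labels = np.array(labels, dtype=object)
    spec = WindowSpec(window_size=1, n_features=2)
    return WindowDataset(vectors, labels, np.arange(len(labels)), spec)


FAST = ClassifierConfig(n_estimators=5, random_seed=0)


class TestPointMetrics:
    def test_worked_example(self):
        # TP=8, FP=2, FN=8 for class "x"
        y_true = ["x"] * 16 + ["y"] * 4
        y_pred = ["x"] * 8 + ["y"] * 8 + ["x"] * 2 + ["y"] * 2
        p, r, f = precision_recall_f1(y_true, y_pred, "x")
        assert p == pytest.approx(0.8)
        assert r == pytest.approx(0.5)
        assert f == pytest.approx(2 / (1 / 0.8 + 1 / 0.5))

    def test_perfect_prediction(self):
        y = ["a", "b", "a"]
        assert precision_recall_f1(y, y, "a") == (1.0, 1.0, 1.0)

    def test_absent_class_scores_zero_by_convention(self):
        assert precision_recall_f1(["a", "a"], ["a", "a"], "b") == (0.0, 0.0, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            precision_recall_f1(["a"], ["a", "b"], "a")

    def test_weighted_f1_worked_example(self):
        y_true = ["a", "a", "a", "b", "b"]
        y_pred = ["a", "a", "a", "b", "a"]
        # a: P=3/4, R=1 -> F1=6/7; b: P=1, R=1/2 -> F1=2/3
        expected = (3 * (6 / 7) + 2 * (2 / 3)) / 5
        assert weighted_f1(y_true, y_pred) == pytest.approx(expected)

    def test_weighted_f1_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            weighted_f1([], [])

    def test_metrics_match_brute_force_tally_on_random_sets(self):
        rng = np.random.default_rng(7)
        classes = np.array(["a", "b", "c", "d"], dtype=object)
        for _ in range(50):
            n = int(rng.integers(3, 60))
            y_true = rng.choice(classes, size=n)
            y_pred = rng.choice(classes, size=n)
            assert weighted_f1(y_true, y_pred) == pytest.approx(
                weighted_f1_tally(list(y_true), list(y_pred)), abs=1e-12
            )
            for cls in classes:
                got = precision_recall_f1(y_true, y_pred, cls)
                want = precision_recall_f1_tally(list(y_true), list(y_pred), cls)
                assert got == pytest.approx(want, abs=1e-12)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = ["a", "b", "a", "b"]
        absolute, relative = confusion(y, y, ("a", "b"))
        np.testing.assert_array_equal(absolute, [[2, 0], [0, 2]])
        np.testing.assert_array_equal(relative, [[1.0, 0.0], [0.0, 1.0]])

    def test_total_confusion_puts_mass_off_diagonal(self):
        absolute, relative = confusion(["a", "a"], ["b", "b"], ("a", "b"))
        np.testing.assert_array_equal(absolute, [[0, 2], [0, 0]])
        assert relative[0, 1] == 1.0
        assert relative[1].sum() == 0.0  # empty row stays zero

    def test_matches_tally_and_marginals(self, rng):
        classes = ("a", "b", "c")
        y_true = rng.choice(classes, size=100)
        y_pred = rng.choice(classes, size=100)
        absolute, relative = confusion(y_true, y_pred, classes)
        np.testing.assert_array_equal(
            absolute, confusion_tally(list(y_true), list(y_pred), classes)
        )
        assert absolute.sum() == 100
        for i, cls in enumerate(classes):
            assert absolute[i].sum() == np.sum(y_true == cls)
            assert relative[i].sum() == pytest.approx(1.0)


class TestFoldStructure:
    def test_even_split(self):
        bounds = fold_boundaries(10)
        assert bounds == [(0, 2), (2, 4), (4, 6), (6, 8), (8, 10)]

    def test_remainder_goes_to_last_block(self):
        bounds = fold_boundaries(11)
        assert bounds[-1] == (8, 11)
        assert [b - a for a, b in bounds] == [2, 2, 2, 2, 3]

    def test_folds_partition_the_range(self):
        for n in (5, 23, 101):
            bounds = fold_boundaries(n)
            covered = [i for a, b in bounds for i in range(a, b)]
            assert covered == list(range(n))

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            fold_boundaries(4)


class TestCrossValidation:
    def test_separable_blocked_data_scores_high(self, blocked_dataset):
        report = cv5_nonshuffled(blocked_dataset, FAST)
        assert len(report.per_fold_weighted_f1) == 5
        assert report.cv_mean == pytest.approx(
            np.mean(report.per_fold_weighted_f1)
        )
        assert report.cv_mean > 0.9

    def test_confusion_sums_to_last_fold_size(self, blocked_dataset):
        report = cv5_nonshuffled(blocked_dataset, FAST)
        assert report.confusion_absolute.sum() == len(blocked_dataset) // 5
        supports = [report.per_class[c]["support"] for c in report.class_order]
        np.testing.assert_array_equal(report.confusion_absolute.sum(axis=1), supports)

    def test_report_serialization(self, blocked_dataset, tmp_path):
        report = cv5_nonshuffled(blocked_dataset, FAST)
        report.save(tmp_path)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "confusion_absolute.csv").exists()


class TestCurves:
    def test_singleton_validation_curve_equals_direct_cv(self, blocked_dataset):
        direct = cv5_nonshuffled(blocked_dataset, FAST)
        curve = validation_curve(blocked_dataset, "n_estimators", [5], FAST)
        assert curve[5]["per_fold"] == direct.per_fold_weighted_f1

    def test_unknown_hyperparameter_rejected(self, blocked_dataset):
        with pytest.raises(ValueError, match="unknown hyperparameter"):
            validation_curve(blocked_dataset, "depth", [1, 2], FAST)

    def test_empty_value_set_rejected(self, blocked_dataset):
        with pytest.raises(ValueError, match="non-empty"):
            validation_curve(blocked_dataset, "n_estimators", [], FAST)

    def test_learning_curve_full_fraction_reproduces_cv(self, blocked_dataset):
        direct = cv5_nonshuffled(blocked_dataset, FAST)
        curve = learning_curve(blocked_dataset, [1.0], FAST)
        assert curve[1.0]["per_fold"] == direct.per_fold_weighted_f1

    def test_learning_curve_improves_with_more_data(self, blocked_dataset):
        curve = learning_curve(blocked_dataset, [0.1, 1.0], FAST)
        assert curve[1.0]["mean"] >= curve[0.1]["mean"] - 0.05

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_invalid_fractions_rejected(self, blocked_dataset, fraction):
        with pytest.raises(ValueError):
            learning_curve(blocked_dataset, [fraction], FAST)
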