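import numpy as np
import pandas as pd
import pytest
from reference_tables import HOCKEY_TUNED, SOCCER_BASELINE

from sportdwt import (ACTIVITY_LABELS, ClassifierSpec, ConfusionMatrix,
                      confusion_matrix, kfold_cv, macro_f_measure,
                      mean_absolute_error, parameter_sweep,
                      precision_recall_f1, repeated_holdout)
from sportdwt.evaluation import StratificationError


def _pairs_from_matrix(counts):
    """Expand a confusion matrix back into (actual, predicted) label pairs."""
    actual, predicted = [], []
    for i, row in enumerate(counts):
        for j, c in enumerate(row):
            actual += [f"A{i + 1}"] * c
            predicted += [f"A{j + 1}"] * c
    return actual, predicted


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = [lab for lab in ACTIVITY_LABELS for _ in range(30)]
        cm = confusion_matrix(labels, labels)
        np.testing.assert_array_equal(cm.counts, np.eye(7, dtype=int) * 30)

    def test_reconstructs_reference_table(self):
        cm = confusion_matrix(*_pairs_from_matrix(SOCCER_BASELINE))
        np.testing.assert_array_equal(cm.counts, SOCCER_BASELINE)
        assert cm.total == 210

    def test_empty_input_gives_zero_matrix(self):
        cm = confusion_matrix([], [])
        assert cm.total == 0
        assert cm.labels == ACTIVITY_LABELS

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix(["A1"], ["B9"], labels=ACTIVITY_LABELS)

    def test_row_sums_are_class_counts(self):
        cm = confusion_matrix(*_pairs_from_matrix(HOCKEY_TUNED))
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [30] * 7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ConfusionMatrix(labels=("A1", "A2"),
                            counts=np.array([[1, -1], [0, 1]]))


class TestPrecisionRecallF1:
    def test_clean_class_scores_one(self):
        # sprinting is classified perfectly in the soccer baseline
        table = precision_recall_f1(
            confusion_matrix(*_pairs_from_matrix(SOCCER_BASELINE)))
        assert table.loc["A4"].tolist() == [1.0, 1.0, 1.0]

    def test_stationary_class_inflated_column(self):
        # A1 column collects 40 predictions for 30 true instances
        table = precision_recall_f1(
            confusion_matrix(*_pairs_from_matrix(SOCCER_BASELINE)))
        assert table.loc["A1", "recall"] == pytest.approx(1.0)
        assert table.loc["A1", "precision"] == pytest.approx(30 / 40)

    def test_absent_class_scores_zero(self):
        cm = confusion_matrix(["A1", "A2"], ["A1", "A2"])
        table = precision_recall_f1(cm)
        assert table.loc["A3"].tolist() == [0.0, 0.0, 0.0]


class TestMacroFMeasure:
    def test_baseline_soccer_reproduces_printed_score(self):
        cm = confusion_matrix(*_pairs_from_matrix(SOCCER_BASELINE))
        assert round(macro_f_measure(cm), 3) == 0.627

    def test_tuned_hockey_reproduces_printed_score(self):
        cm = confusion_matrix(*_pairs_from_matrix(HOCKEY_TUNED))
        assert round(macro_f_measure(cm), 3) == 0.823

    def test_perfect_matrix_scores_one(self):
        labels = [lab for lab in ACTIVITY_LABELS for _ in range(5)]
        assert macro_f_measure(confusion_matrix(labels, labels)) == 1.0


class TestMeanAbsoluteError:
    def test_perfect_one_hot_is_zero(self):
        actual = ["A1", "A5"]
        probs = pd.DataFrame(0.0, index=range(2), columns=ACTIVITY_LABELS)
        probs.loc[0, "A1"] = 1.0
        probs.loc[1, "A5"] = 1.0
        assert mean_absolute_error(probs, actual) == 0.0

    def test_uniform_predictions_closed_form(self):
        probs = pd.DataFrame(1 / 7, index=range(5), columns=ACTIVITY_LABELS)
        assert mean_absolute_error(probs, ["A3"] * 5) == \
            pytest.approx(12 / 49)

    def test_confidently_wrong_one_hot(self):
        probs = pd.DataFrame(0.0, index=range(3), columns=ACTIVITY_LABELS)
        probs["A2"] = 1.0
        assert mean_absolute_error(probs, ["A1"] * 3) == pytest.approx(2 / 7)

    def test_invalid_distribution_rejected(self):
        probs = pd.DataFrame(0.3, index=range(2), columns=ACTIVITY_LABELS)
        with pytest.raises(ValueError, match="sums to"):
            mean_absolute_error(probs, ["A1", "A2"])


class TestRepeatedHoldout:
    def test_deterministic_given_seed(self, blobs_7class, spec_nb):
        X, y = blobs_7class
        r1 = repeated_holdout(X, y, spec_nb, reps=3, seed=5)
        r2 = repeated_holdout(X, y, spec_nb, reps=3, seed=5)
        assert r1.macro_f == r2.macro_f
        np.testing.assert_array_equal(r1.confusion.counts,
                                      r2.confusion.counts)

    def test_separable_data_perfect_every_rep(self, blobs_7class, spec_nb):
        X, y = blobs_7class
        report = repeated_holdout(X, y, spec_nb, reps=4, seed=0)
        assert report.macro_f == 1.0
        assert report.metadata["per_rep_macro_f"] == [1.0] * 4

    def test_single_rep_is_single_split(self, blobs_7class, spec_nb):
        X, y = blobs_7class
        report = repeated_holdout(X, y, spec_nb, reps=1, seed=3)
        assert len(report.metadata["per_rep_macro_f"]) == 1
        assert report.macro_f == report.metadata["per_rep_macro_f"][0]

    def test_averaged_macro_within_rep_range(self, soccer_high_Xy):
        X, y = soccer_high_Xy
        report = repeated_holdout(X, y, ClassifierSpec("knn", seed=0),
                                  reps=4, seed=1)
        reps = report.metadata["per_rep_macro_f"]
        assert min(reps) - 1e-12 <= report.macro_f <= max(reps) + 1e-12

    def test_macro_is_mean_of_per_class_f1(self, soccer_high_Xy):
        X, y = soccer_high_Xy
        report = repeated_holdout(X, y, ClassifierSpec("knn", seed=0),
                                  reps=2, seed=1)
        assert report.macro_f == pytest.approx(
            report.per_class["f1"].mean(), abs=1e-12)

    def test_small_class_rejected(self, spec_nb):
        X = pd.DataFrame({"f": np.arange(10.0)})
        y = pd.Series(["A1"] * 9 + ["A2"])
        with pytest.raises(StratificationError):
            repeated_holdout(X, y, spec_nb)


class TestKFoldCV:
    def test_separable_data_perfect(self, blobs_7class, spec_nb):
        X, y = blobs_7class
        assert kfold_cv(X, y, spec_nb, k=4, seed=0).macro_f == 1.0

    def test_every_instance_tested_once(self, blobs_7class, spec_nb):
        X, y = blobs_7class
        report = kfold_cv(X, y, spec_nb, k=4, seed=0)
        assert report.confusion.total == len(X)
        np.testing.assert_array_equal(
            report.confusion.counts.sum(axis=1),
            [int((y == lab).sum()) for lab in sorted(y.unique())])

    def test_too_many_folds_rejected(self, spec_nb):
        X = pd.DataFrame({"f": np.arange(8.0)})
        y = pd.Series(["A1", "A2"] * 4)
        with pytest.raises(StratificationError):
            kfold_cv(X, y, spec_nb, k=10)


class TestParameterSweep:
    def test_singleton_grid_matches_repeated_holdout(self, soccer_high_logs):
        result = parameter_sweep(soccer_high_logs, ["naive_bayes"], ["db4"],
                                 [2], [5.0], seed=3, reps=2)
        assert len(result.cells) == 1
        cell = result.cells.iloc[0]
        report = result.reports[("naive_bayes", "db4", 2, 5.0)]
        assert cell["macro_f"] == report.macro_f
        assert result.marginal_means("level")[2] == cell["macro_f"]

    def test_cell_count_is_grid_product(self, soccer_high_logs):
        result = parameter_sweep(soccer_high_logs[:70],
                                 ["knn", "naive_bayes"], ["haar", "db2"],
                                 [1, 2], [3.0], seed=0, reps=1)
        assert len(result.cells) == 8

    def test_marginal_means_recompute_from_cells(self, soccer_high_logs):
        result = parameter_sweep(soccer_high_logs[:70], ["knn"],
                                 ["haar", "db2"], [1, 2], [3.0],
                                 seed=0, reps=1)
        for axis in ("wavelet", "level"):
            expected = result.cells.groupby(axis)["macro_f"].mean()
            pd.testing.assert_series_equal(result.marginal_means(axis),
                                           expected)

    def test_empty_axis_rejected(self, soccer_high_logs):
        with pytest.raises(ValueError, match="empty"):
            parameter_sweep(soccer_high_logs, [], ["db4"], [2], [5.0])

    def test_long_windows_mix_surrounding_play(self, soccer_high_logs):
        """Windows reaching past the clean central span score no better."""
        result = parameter_sweep(soccer_high_logs, ["naive_bayes"], ["db4"],
                                 [2], [5.0, 9.0], seed=5, reps=5)
        cells = result.cells.set_index("window_length")["macro_f"]
        assert cells[9.0] <= cells[5.0] + 0.01
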