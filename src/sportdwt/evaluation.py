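"""Evaluation protocol: confusion matrices, macro F-measure, MAE, repeated
holdout, cross-validation, and the parameter sweep.

The protocol follows common practice for small balanced activity datasets:
two thirds of the data train the model, the rest tests it, and the split is
re-randomized 10 times with the per-split scores averaged; the strongest
configurations are additionally checked with stratified 10-fold
cross-validation.  Scores are macro-averaged F-measures — the unweighted
mean over classes of F1 = 2PR/(P+R) with P = Tp/(Tp+Fp), R = Tp/(Tp+Fn) —
plus the mean absolute error of the predicted class-probability vectors
against one-hot truth.

The parameter sweep crosses classifier family x mother wavelet x
decomposition level x window length, evaluates every cell by repeated
holdout, and reports per-axis marginal means alongside the best cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .features import feature_table, split_feature_table
from .models import ClassifierSpec, train, train_fusion
from .signals import ACTIVITY_LABELS, ActivityLog, segment_dataset


class StratificationError(ValueError):
    """A class has too few instances to stratify the requested splits."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows are actual labels, columns predicted, in a fixed label order."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.labels)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


def confusion_matrix(actual: Sequence[str], predicted: Sequence[str],
                     labels: Sequence[str] | None = None) -> ConfusionMatrix:
    """Count (actual, predicted) label pairs.

    ``labels`` fixes the row/column order; by default the seven activity
    labels are used when they cover the data, otherwise the sorted label
    set.  Labels outside the given order raise ``ValueError``.
    """
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    seen = set(actual) | set(predicted)
    if labels is None:
        labels = ACTIVITY_LABELS if seen <= set(ACTIVITY_LABELS) else \
            tuple(sorted(seen))
    unknown = seen - set(labels)
    if unknown:
        raise ValueError(f"labels outside the declared order: {sorted(unknown)}")
    pos = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, p in zip(actual, predicted):
        counts[pos[a], pos[p]] += 1
    return ConfusionMatrix(labels=tuple(labels), counts=counts)


def precision_recall_f1(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision, recall and F1 (0 when a denominator is 0)."""
    c = cm.counts.astype(float)
    tp = np.diag(c)
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        r = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        f1 = np.where(p + r > 0, 2 * p * r / np.where(p + r > 0, p + r, 1), 0.0)
    return pd.DataFrame({"precision": p, "recall": r, "f1": f1},
                        index=list(cm.labels))


def macro_f_measure(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the per-class F1 scores."""
    return float(precision_recall_f1(cm)["f1"].mean())


def mean_absolute_error(prob_rows: pd.DataFrame | Sequence[Mapping[str, float]],
                        actual: Sequence[str],
                        labels: Sequence[str] = ACTIVITY_LABELS,
                        tol: float = 1e-6) -> float:
    """MAE of class-probability vectors against one-hot truth.

    MAE = (1/(n k)) sum_instances sum_classes |p_c - 1{c = actual}|.
    Uniform 1/k predictions give 2(k-1)/k^2 (~0.2449 for k = 7).
    """
    probs = pd.DataFrame(list(prob_rows)) if not isinstance(prob_rows, pd.DataFrame) \
        else prob_rows
    probs = probs[list(labels)]
    sums = probs.sum(axis=1).to_numpy()
    if np.any(np.abs(sums - 1.0) > tol):
        bad = int(np.argmax(np.abs(sums - 1.0) > tol))
        raise ValueError(
            f"probability row {bad} sums to {sums[bad]:.6f}, not 1"
        )
    onehot = np.zeros(probs.shape)
    pos = {lab: i for i, lab in enumerate(labels)}
    for i, a in enumerate(actual):
        onehot[i, pos[a]] = 1.0
    return float(np.abs(probs.to_numpy() - onehot).mean())


@dataclass
class EvaluationReport:
    """Confusion matrix, per-class P/R/F1, macro F and MAE for one run.

    For averaged reports (repeated holdout) ``confusion`` is the sum of the
    per-split matrices, ``per_class`` the mean of the per-split tables, and
    ``macro_f``/``mae`` the means of the per-split scores.
    """

    confusion: ConfusionMatrix
    per_class: pd.DataFrame
    macro_f: float
    mae: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.confusion.labels),
            "confusion": self.confusion.counts.tolist(),
            "per_class": self.per_class.round(6).to_dict(),
            "macro_f": self.macro_f,
            "mae": self.mae,
            "metadata": {k: v for k, v in self.metadata.items()
                         if not k.startswith("_")},
        }


def _fit_predict(spec: ClassifierSpec, X_train: pd.DataFrame, y_train,
                 X_test: pd.DataFrame, fusion: bool,
                 labels: Sequence[str]) -> tuple[np.ndarray, pd.DataFrame]:
    if fusion:
        model = train_fusion(spec, X_train, y_train, activity_labels=labels)
        proba = model.predict_proba_table(X_test)
        pred = proba.columns.to_numpy()[np.argmax(proba.to_numpy(), axis=1)]
        return pred, proba
    model = train(spec, X_train, y_train)
    proba = model.predict_proba_table(X_test)
    pred = model.predict(X_test)
    return pred, proba


def _single_report(spec, X, y, train_idx, test_idx, fusion, labels,
                   ) -> EvaluationReport:
    pred, proba = _fit_predict(
        spec, X.iloc[train_idx], y[train_idx], X.iloc[test_idx], fusion, labels
    )
    actual = y[test_idx]
    cm = confusion_matrix(actual, pred, labels=labels)
    per_class = precision_recall_f1(cm)
    present = sorted(set(labels) & set(proba.columns))
    mae = mean_absolute_error(proba, actual, labels=present) \
        if len(present) == len(labels) else float("nan")
    return EvaluationReport(
        confusion=cm,
        per_class=per_class,
        macro_f=float(per_class["f1"].mean()),
        mae=mae,
        metadata={"n_train": len(train_idx), "n_test": len(test_idx)},
    )


def _check_stratifiable(y: np.ndarray, minimum: int) -> None:
    vals, counts = np.unique(y, return_counts=True)
    if counts.min() < minimum:
        lab = vals[int(np.argmin(counts))]
        raise StratificationError(
            f"class {lab!r} has {counts.min()} instance(s); at least "
            f"{minimum} are needed for stratified splitting"
        )


def repeated_holdout(features: pd.DataFrame, labels: Sequence[str],
                     spec: ClassifierSpec, reps: int = 10,
                     train_fraction: float = 2 / 3, seed: int = 0,
                     fusion: bool = False,
                     class_labels: Sequence[str] | None = None
                     ) -> EvaluationReport:
    """Average ``reps`` stratified random train/test splits.

    Per-split reports are kept in ``metadata['reports']``; the averaged
    report sums the confusion matrices and averages per-class scores,
    macro F and MAE.  Split seeds derive deterministically from ``seed``.
    """
    y = np.asarray(labels)
    if class_labels is None:
        class_labels = tuple(sorted(np.unique(y)))
    _check_stratifiable(y, 2)
    splitter = StratifiedShuffleSplit(
        n_splits=reps, train_size=train_fraction, random_state=seed % 2**31
    )
    reports = [
        _single_report(spec, features, y, tr, te, fusion, class_labels)
        for tr, te in splitter.split(features, y)
    ]
    return _aggregate(reports, {
        "protocol": "repeated_holdout", "reps": reps,
        "train_fraction": train_fraction, "seed": seed,
        "family": spec.family, "fusion": fusion,
    })


def kfold_cv(features: pd.DataFrame, labels: Sequence[str],
             spec: ClassifierSpec, k: int = 10, seed: int = 0,
             fusion: bool = False,
             class_labels: Sequence[str] | None = None) -> EvaluationReport:
    """Stratified k-fold cross-validation, folds pooled into one report."""
    y = np.asarray(labels)
    if class_labels is None:
        class_labels = tuple(sorted(np.unique(y)))
    _check_stratifiable(y, k)
    splitter = StratifiedKFold(n_splits=k, shuffle=True,
                               random_state=seed % 2**31)
    actual_all: list[str] = []
    pred_all: list[str] = []
    proba_all: list[pd.DataFrame] = []
    for tr, te in splitter.split(features, y):
        pred, proba = _fit_predict(
            spec, features.iloc[tr], y[tr], features.iloc[te], fusion,
            class_labels,
        )
        actual_all += list(y[te])
        pred_all += list(pred)
        proba_all.append(proba)
    cm = confusion_matrix(actual_all, pred_all, labels=class_labels)
    per_class = precision_recall_f1(cm)
    proba = pd.concat(proba_all, ignore_index=True)
    return EvaluationReport(
        confusion=cm,
        per_class=per_class,
        macro_f=float(per_class["f1"].mean()),
        mae=mean_absolute_error(proba, actual_all, labels=class_labels),
        metadata={"protocol": "kfold_cv", "k": k, "seed": seed,
                  "family": spec.family, "fusion": fusion},
    )


def _aggregate(reports: list[EvaluationReport], metadata: dict
               ) -> EvaluationReport:
    counts = sum(r.confusion.counts for r in reports)
    labels = reports[0].confusion.labels
    per_class = sum(r.per_class for r in reports) / len(reports)
    macro = float(per_class["f1"].mean())
    maes = [r.mae for r in reports]
    meta = dict(metadata)
    meta["per_rep_macro_f"] = [r.macro_f for r in reports]
    meta["_reports"] = reports
    return EvaluationReport(
        confusion=ConfusionMatrix(labels=labels, counts=counts),
        per_class=per_class,
        macro_f=macro,
        mae=float(np.mean(maes)),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Grid evaluation over family x wavelet x level x window length."""

    cells: pd.DataFrame        # one row per grid cell with macro_f and mae
    reports: dict[tuple, EvaluationReport]

    AXES = ("family", "wavelet", "level", "window_length")

    def marginal_means(self, axis: str) -> pd.Series:
        """Mean macro F over all cells sharing each value of one axis."""
        if axis not in self.AXES:
            raise ValueError(f"axis must be one of {self.AXES}")
        return self.cells.groupby(axis)["macro_f"].mean()

    def best_cell(self) -> pd.Series:
        """The grid cell with the highest macro F (first under ties)."""
        return self.cells.loc[self.cells["macro_f"].idxmax()]


def parameter_sweep(logs: Sequence[ActivityLog],
                    families: Sequence[str],
                    wavelets: Sequence[str],
                    levels: Sequence[int],
                    window_lengths: Sequence[float],
                    seed: int = 0, reps: int = 10,
                    train_fraction: float = 2 / 3) -> SweepResult:
    """Evaluate every grid cell by repeated holdout on the given logs.

    Features are re-extracted per (wavelet, level, window length); the
    classifier axis reuses each feature table.  Cell seeds derive
    deterministically from ``seed``.
    """
    for name, axis in (("families", families), ("wavelets", wavelets),
                       ("levels", levels), ("window_lengths", window_lengths)):
        if not len(axis):
            raise ValueError(f"sweep axis {name} is empty")
    rows = []
    reports: dict[tuple, EvaluationReport] = {}
    cell_index = 0
    for length in window_lengths:
        windows = segment_dataset(logs, length)
        for wavelet in wavelets:
            for level in levels:
                table = feature_table(windows, wavelet, level)
                X, y = split_feature_table(table)
                for family in families:
                    cell_seed = (seed * 1_000_003 + cell_index) % 2**31
                    cell_index += 1
                    spec = ClassifierSpec(family=family, seed=cell_seed)
                    report = repeated_holdout(
                        X, y, spec, reps=reps,
                        train_fraction=train_fraction, seed=cell_seed,
                    )
                    key = (family, wavelet, level, length)
                    reports[key] = report
                    rows.append({
                        "family": family, "wavelet": wavelet,
                        "level": level, "window_length": length,
                        "macro_f": report.macro_f, "mae": report.mae,
                    })
    return SweepResult(cells=pd.DataFrame(rows), reports=reports)
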