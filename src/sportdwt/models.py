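"""Classifier families behind a single train/predict contract.

Five families are supported, mirroring the toolkits commonly used for
accelerometer-based activity recognition:

* ``svm_smo`` — linear support vector machine (C = 1) with Platt-style
  probability calibration, so its confidences are comparable across models;
* ``knn`` — k-nearest neighbours (k = 1, Euclidean);
* ``naive_bayes`` — Gaussian naive Bayes;
* ``logistic_model_tree`` — an approximation of the logistic model tree: a
  shallow CART whose leaves hold multinomial-logistic models (falling back
  to smoothed class proportions in degenerate leaves);
* ``mlp`` — one-hidden-layer perceptron with (n_features + n_classes) / 2
  units trained by backpropagation for up to 500 epochs.

Scale-sensitive families (svm_smo, knn, mlp) standardize features with
train-set statistics inside the fitted model; naive_bayes and the tree
consume raw features.  Every family honours ``ClassifierSpec.seed``, so
training and prediction are deterministic given the spec.

For classifier fusion a separate binary model is trained per activity
(one-vs-rest); at prediction time the activity whose model reports the
highest positive-class confidence wins, ties going to the lowest activity
index.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .signals import ACTIVITY_LABELS

CLASSIFIER_FAMILIES = (
    "svm_smo", "knn", "naive_bayes", "logistic_model_tree", "mlp",
)

_REST = "__rest__"


class TrainingError(ValueError):
    """Raised when the training data cannot support the requested model."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Family name, hyperparameter overrides and a seed."""

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from "
                f"{CLASSIFIER_FAMILIES}"
            )


class LogisticModelTreeApprox(BaseEstimator, ClassifierMixin):
    """Decision tree with multinomial-logistic models at the leaves.

    A stand-in for the classic logistic model tree: the CART split
    structure performs the stage-wise attribute selection, and each leaf
    refines its region with a multinomial logistic fit.  Leaves that are
    pure or too small fall back to Laplace-smoothed class proportions.
    """

    def __init__(self, max_depth: int = 3, min_samples_leaf: int = 15,
                 C: float = 1.0, random_state: int | None = None):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.tree_ = DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        ).fit(X, y)
        self.leaf_models_: dict[int, object] = {}
        self.leaf_priors_: dict[int, np.ndarray] = {}
        leaves = self.tree_.apply(X)
        k = len(self.classes_)
        for leaf in np.unique(leaves):
            mask = leaves == leaf
            y_leaf = y[mask]
            counts = np.array([(y_leaf == c).sum() for c in self.classes_],
                              dtype=float)
            self.leaf_priors_[leaf] = (counts + 1.0) / (counts.sum() + k)
            if len(np.unique(y_leaf)) >= 2 and mask.sum() >= 2 * k:
                lr = LogisticRegression(
                    C=self.C, max_iter=500, random_state=self.random_state
                )
                self.leaf_models_[leaf] = lr.fit(X[mask], y_leaf)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        leaves = self.tree_.apply(X)
        out = np.zeros((len(X), len(self.classes_)))
        pos = {c: i for i, c in enumerate(self.classes_)}
        for leaf in np.unique(leaves):
            mask = leaves == leaf
            model = self.leaf_models_.get(leaf)
            if model is None:
                out[mask] = self.leaf_priors_[leaf]
            else:
                proba = model.predict_proba(X[mask])
                for j, c in enumerate(model.classes_):
                    out[mask, pos[c]] = proba[:, j]
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _build_estimator(spec: ClassifierSpec, n_features: int,
                     n_classes: int) -> BaseEstimator:
    hp = dict(spec.hyperparameters)
    if spec.family == "svm_smo":
        svc = SVC(
            kernel=hp.pop("kernel", "linear"),
            C=hp.pop("C", 1.0),
            random_state=spec.seed,
            **hp,
        )
        # sigmoid (Platt) calibration turns margins into probabilities
        est = CalibratedClassifierCV(svc, method="sigmoid", cv=5,
                                     ensemble=False)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if spec.family == "knn":
        est = KNeighborsClassifier(
            n_neighbors=hp.pop("k", hp.pop("n_neighbors", 1)), **hp
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if spec.family == "naive_bayes":
        return GaussianNB(**hp)
    if spec.family == "logistic_model_tree":
        return LogisticModelTreeApprox(random_state=spec.seed, **hp)
    if spec.family == "mlp":
        # (features + classes) / 2 hidden units, floored at 4 so tiny
        # toy problems still get a workable net
        hidden = hp.pop("hidden_units", max(4, (n_features + n_classes) // 2))
        est = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            max_iter=hp.pop("epochs", 500),
            random_state=spec.seed,
            **hp,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    raise AssertionError(spec.family)


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to apply it safely."""

    spec: ClassifierSpec
    estimator: BaseEstimator
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    n_training_rows: int

    def _check_features(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = set(self.feature_names) - set(X.columns)
        if missing:
            raise ValueError(
                f"feature columns missing at prediction time: {sorted(missing)}"
            )
        return X[list(self.feature_names)]

    def predict_proba_table(self, X: pd.DataFrame) -> pd.DataFrame:
        """Class-probability rows (one column per training label)."""
        X = self._check_features(X)
        proba = self.estimator.predict_proba(X.to_numpy(dtype=float))
        cols = list(self.estimator.classes_) if hasattr(self.estimator, "classes_") \
            else list(self.estimator[-1].classes_)
        out = pd.DataFrame(proba, columns=cols, index=X.index)
        return out[list(self.classes)]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.predict_proba_table(X)
        return proba.columns.to_numpy()[np.argmax(proba.to_numpy(), axis=1)]


def train(spec: ClassifierSpec, features: pd.DataFrame,
          labels: Sequence[str]) -> TrainedModel:
    """Fit one model; deterministic given ``spec.seed``.

    Raises :class:`TrainingError` for single-class data and ``ValueError``
    for missing feature values.
    """
    y = np.asarray(labels)
    if features.isna().any().any():
        raise ValueError("feature table contains missing (NaN) values")
    classes = tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise TrainingError("training data must contain at least 2 classes")
    est = _build_estimator(spec, features.shape[1], len(classes))
    est.fit(features.to_numpy(dtype=float), y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        classes=classes,
        feature_names=tuple(features.columns),
        n_training_rows=len(features),
    )


def predict_proba(model: TrainedModel, row: pd.Series | Mapping[str, float]
                  ) -> dict[str, float]:
    """Probability map for a single feature row."""
    frame = pd.DataFrame([dict(row)])
    proba = model.predict_proba_table(frame).iloc[0]
    return {str(k): float(v) for k, v in proba.items()}


# ---------------------------------------------------------------------------
# One-vs-rest fusion
# ---------------------------------------------------------------------------

@dataclass
class FusionModel:
    """One binary (activity-vs-rest) model per label, fused by confidence."""

    models: dict[str, TrainedModel]
    labels: tuple[str, ...] = ACTIVITY_LABELS

    def __post_init__(self) -> None:
        if set(self.models) != set(self.labels):
            raise TrainingError(
                f"fusion needs exactly one model per label in {self.labels}"
            )

    def confidences(self, X: pd.DataFrame) -> pd.DataFrame:
        """Positive-class confidence of each per-activity model."""
        cols = {}
        for label in self.labels:
            proba = self.models[label].predict_proba_table(X)
            cols[label] = proba[label]
        return pd.DataFrame(cols, index=X.index)

    def predict_proba_table(self, X: pd.DataFrame) -> pd.DataFrame:
        """Confidences renormalized to a distribution over activities."""
        conf = self.confidences(X)
        total = conf.sum(axis=1)
        uniform = 1.0 / len(self.labels)
        out = conf.div(total.where(total > 0, 1.0), axis=0)
        out[total <= 0] = uniform
        return out


def train_fusion(spec_per_activity: Mapping[str, ClassifierSpec] | ClassifierSpec,
                 features: pd.DataFrame, labels: Sequence[str],
                 activity_labels: Sequence[str] = ACTIVITY_LABELS
                 ) -> FusionModel:
    """Train one activity-vs-rest binary model per label.

    A single spec may be given to use the same family for all seven
    models.  Every activity must appear at least twice in ``labels``.
    """
    y = np.asarray(labels)
    if isinstance(spec_per_activity, ClassifierSpec):
        specs = {lab: spec_per_activity for lab in activity_labels}
    else:
        specs = dict(spec_per_activity)
        if set(specs) != set(activity_labels):
            raise TrainingError("one ClassifierSpec per activity is required")
    models: dict[str, TrainedModel] = {}
    for label in activity_labels:
        n_pos = int((y == label).sum())
        if n_pos == 0:
            raise TrainingError(f"label {label} absent from training data")
        if n_pos < 2:
            raise TrainingError(
                f"label {label} has a single training example; cannot train "
                f"a one-vs-rest model"
            )
        y_bin = np.where(y == label, label, _REST)
        models[label] = train(specs[label], features, y_bin)
    return FusionModel(models=models, labels=tuple(activity_labels))


def fuse_predict(fusion: FusionModel, row: pd.Series | Mapping[str, float]
                 ) -> tuple[str, float]:
    """Predict one row: the activity with the highest binary confidence.

    Exact ties resolve to the lowest activity index (A1 < ... < A7).
    """
    frame = pd.DataFrame([dict(row)])
    conf = fusion.confidences(frame).iloc[0]
    best_val = float(conf.max())
    for lab in fusion.labels:  # first maximum wins ties (A1 < ... < A7)
        if conf[lab] == best_val:
            return lab, best_val
    raise AssertionError("unreachable")


def save_model(model: TrainedModel | FusionModel, path: str | Path) -> None:
    """Persist a model (spec, fitted state, feature names) to disk."""
    with open(Path(path), "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> TrainedModel | FusionModel:
    with open(Path(path), "rb") as fh:
        return pickle.load(fh)
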