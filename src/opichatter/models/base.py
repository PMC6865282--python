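"""Classifier specs, training and prediction for the six model families."""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from ..corpus import ClassLabel, LABELS
from .cnn import TextCNN
from .resample import resample

__all__ = ["ClassifierSpec", "TrainedModel", "train", "predict", "grid_search"]

FAMILIES = ("naive_bayes", "decision_tree", "knn", "random_forest", "svm", "cnn")
RESAMPLING = ("none", "random_under", "random_over", "smote")

_LABEL_ORDER = {lab.value: i for i, lab in enumerate(LABELS)}


@dataclass
class ClassifierSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    resampling: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected {FAMILIES}")
        if self.resampling not in RESAMPLING:
            raise ValueError(
                f"unknown resampling {self.resampling!r}; expected {RESAMPLING}"
            )


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "naive_bayes":
        return MultinomialNB(**{"alpha": 1.0, **hp})
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.family == "knn":
        return KNeighborsClassifier(**{"n_neighbors": 5, **hp})
    if spec.family == "random_forest":
        return RandomForestClassifier(
            random_state=spec.seed, **{"n_estimators": 100, **hp}
        )
    if spec.family == "svm":
        return LinearSVC(random_state=spec.seed, **{"C": 1.0, **hp})
    raise AssertionError(spec.family)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    classes: list[str]
    n_features: int

    def predict(self, features) -> list[ClassLabel]:
        return predict(self, features)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "model": self}, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        return payload["model"]


def _check_xy(features, labels) -> np.ndarray:
    y = np.asarray([str(l) for l in labels], dtype=object)
    n = features.shape[0]
    if n != y.shape[0]:
        raise ValueError(f"{n} feature rows vs {y.shape[0]} labels")
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class; cannot train")
    return y


def train(
    spec: ClassifierSpec,
    features,
    labels: Sequence,
    val_features=None,
    val_labels: Optional[Sequence] = None,
) -> TrainedModel:
    """Fit one classifier per ``spec``, applying its resampling strategy first.

    ``features`` is a sparse/dense matrix for the traditional families and an
    integer id-sequence matrix (n, max_len) for the CNN.  Deterministic for a
    fixed ``spec.seed``.
    """
    y = _check_xy(features, labels)
    X = features
    if spec.resampling != "none":
        X, y = resample(X, y, spec.resampling, seed=spec.seed)
        if spec.family == "cnn":  # id sequences must stay integral
            X = np.clip(np.rint(np.asarray(X, dtype=float)), 0, None).astype(np.int64)
    classes = sorted(set(y), key=lambda v: _LABEL_ORDER.get(v, 99))
    if spec.family == "cnn":
        X = np.asarray(X, dtype=np.int64)
        class_index = {c: i for i, c in enumerate(classes)}
        y_int = np.asarray([class_index[v] for v in y])
        hp = dict(spec.hyperparameters)
        vocab_size = int(hp.pop("vocab_size", int(X.max()) + 1))
        net = TextCNN(
            vocab_size=vocab_size,
            n_classes=len(classes),
            max_len=X.shape[1],
            seed=spec.seed,
            **hp,
        )
        val_ids = val_y = None
        if val_features is not None and val_labels is not None:
            val_ids = np.asarray(val_features, dtype=np.int64)
            val_y = np.asarray(
                [class_index.get(str(l), -1) for l in val_labels]
            )
        net.fit(X, y_int, val_ids, val_y)
        return TrainedModel(spec, net, classes, X.shape[1])
    est = _build_estimator(spec)
    est.fit(X, y)
    return TrainedModel(spec, est, list(est.classes_), features.shape[1])


def predict(model: TrainedModel, features) -> list[ClassLabel]:
    """One :class:`ClassLabel` per feature row."""
    if features.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {features.shape[1]} != trained {model.n_features}"
        )
    if model.spec.family == "cnn":
        ids = np.asarray(features, dtype=np.int64)
        pred = model.estimator.predict(ids)
        return [ClassLabel(model.classes[i]) for i in pred]
    return [ClassLabel(v) for v in model.estimator.predict(features)]


DEFAULT_GRIDS = {
    "naive_bayes": {"alpha": [0.1, 0.5, 1.0]},
    "decision_tree": {"max_depth": [None, 20, 50]},
    "knn": {"n_neighbors": [3, 5, 9]},
    "random_forest": {"n_estimators": [50, 100]},
    "svm": {"C": [0.1, 1.0, 10.0]},
}


def grid_search(
    spec: ClassifierSpec,
    features,
    labels: Sequence,
    grid: Optional[dict] = None,
    cv: int = 10,
) -> ClassifierSpec:
    """10-fold cross-validated grid search over hyperparameters for the
    traditional families; returns a spec with the best values filled in.
    The CNN tunes via validation-set early stopping instead."""
    if spec.family == "cnn":
        raise ValueError("CNN hyperparameters are tuned via validation early stopping")
    y = _check_xy(features, labels)
    grid = grid if grid is not None else DEFAULT_GRIDS[spec.family]
    search = GridSearchCV(_build_estimator(spec), grid, cv=cv, scoring="accuracy")
    search.fit(features, y)
    best = dict(spec.hyperparameters)
    best.update(search.best_params_)
    return ClassifierSpec(spec.family, best, spec.resampling, spec.seed)
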