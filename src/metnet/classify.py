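"""Distance-based classification of graph collections.

Each graph is represented by its row of the pairwise network-distance
(Gram) matrix — its vector of distances to every graph in the
collection — or, alternatively, by an externally produced embedding
vector. Classification uses a linear-kernel SVM (C = 1 by default) with
class weights balanced inversely to class frequency and a one-vs-rest
scheme for more than two classes. Features are min-max normalised with
statistics fitted on training rows only, so no information leaks from
held-out samples into the scaling.

Three evaluation protocols are provided:

* :func:`evaluate_cv` — stratified k-fold cross-validation repeated
  several times with different shuffles (default 10 x 10); metrics are
  computed per repeat from the pooled out-of-fold predictions and
  reported as mean +/- sd across repeats;
* :func:`evaluate_holdout` — a single fit on flagged training graphs
  and evaluation on the held-out test graphs, with test features
  restricted to distances-to-training-graphs only;
* :func:`evaluate_embeddings` — one pass of stratified k-fold CV on
  per-graph feature vectors.

Reported metrics: accuracy, macro-averaged precision / recall / F1 (all
as percentages) and the Matthews correlation coefficient (multi-class
generalisation; sklearn's implementation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    matthews_corrcoef,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .netdist import DistanceMatrix

__all__ = [
    "LabeledCollection",
    "EvaluationReport",
    "evaluate_cv",
    "evaluate_holdout",
    "evaluate_embeddings",
]

METRICS = ("accuracy", "precision", "recall", "f1", "mcc")


@dataclass(frozen=True)
class LabeledCollection:
    """Class labels (and optional train/test split flags) per graph."""

    graph_ids: tuple[str, ...]
    labels: tuple[str, ...]
    split: tuple[str, ...] | None = None  # "train" | "test" per graph

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.graph_ids):
            raise ValueError("labels must align with graph_ids")
        if any(not lab for lab in self.labels):
            raise ValueError("labels must be non-empty")
        if self.split is not None:
            if len(self.split) != len(self.graph_ids):
                raise ValueError("split flags must align with graph_ids")
            bad = set(self.split) - {"train", "test"}
            if bad:
                raise ValueError(f"unknown split flags: {sorted(bad)}")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))

    def aligned_to(self, graph_ids: Sequence[str]) -> "LabeledCollection":
        """Reorder to a given graph-id order (e.g. a DistanceMatrix's)."""
        pos = {g: i for i, g in enumerate(self.graph_ids)}
        missing = [g for g in graph_ids if g not in pos]
        if missing:
            raise ValueError(f"graphs without labels: {missing[:5]}")
        idx = [pos[g] for g in graph_ids]
        return LabeledCollection(
            graph_ids=tuple(graph_ids),
            labels=tuple(self.labels[i] for i in idx),
            split=None if self.split is None else tuple(self.split[i] for i in idx),
        )


@dataclass
class EvaluationReport:
    """Per-repeat and aggregate classification scores.

    ``mean``/``sd`` hold, for each metric in :data:`METRICS`, the mean
    and standard deviation across repeats; accuracy, precision, recall
    and F1 are percentages, MCC lies in [-1, 1].
    """

    per_repeat: list[dict[str, float]]
    seeds: list[int] = field(default_factory=list)

    @property
    def mean(self) -> dict[str, float]:
        return {
            m: float(np.mean([r[m] for r in self.per_repeat])) for m in METRICS
        }

    @property
    def sd(self) -> dict[str, float]:
        return {
            m: float(np.std([r[m] for r in self.per_repeat])) for m in METRICS
        }

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "per_repeat": self.per_repeat,
            "seeds": self.seeds,
        }

    def summary(self) -> str:
        mean, sd = self.mean, self.sd
        parts = []
        for m in METRICS:
            unit = "" if m == "mcc" else "%"
            parts.append(f"{m}: {mean[m]:.2f}{unit} +/- {sd[m]:.2f}")
        return ", ".join(parts)


def _make_classifier(n_classes: int, C: float):
    svm = SVC(kernel="linear", C=C, class_weight="balanced")
    return OneVsRestClassifier(svm) if n_classes > 2 else svm


def _fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    n_classes: int,
    C: float,
) -> np.ndarray:
    scaler = MinMaxScaler().fit(X_train)
    clf = _make_classifier(n_classes, C)
    clf.fit(scaler.transform(X_train), y_train)
    return clf.predict(scaler.transform(X_test))


def _score(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0
    )
    if len(set(y_true)) < 2:
        warnings.warn(
            "MCC is undefined for a single-class truth; reported as 0",
            UserWarning,
            stacklevel=3,
        )
        mcc = 0.0
    else:
        mcc = float(matthews_corrcoef(y_true, y_pred))
    return {
        "accuracy": 100.0 * accuracy_score(y_true, y_pred),
        "precision": 100.0 * precision,
        "recall": 100.0 * recall,
        "f1": 100.0 * f1,
        "mcc": mcc,
    }


def _cv_once(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    rng_seed: int,
    n_classes: int,
    C: float,
) -> dict[str, float]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    y_pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(X, y):
        y_pred[test_idx] = _fit_predict(
            X[train_idx], y[train_idx], X[test_idx], n_classes, C
        )
    return _score(y, y_pred)


def evaluate_cv(
    D: DistanceMatrix,
    labels: LabeledCollection,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> EvaluationReport:
    """Repeated stratified k-fold CV on distance-vector features.

    Each sample's feature vector is its row of the Gram matrix. The
    k-fold split is re-drawn for every repeat with seed ``seed + r``
    (recorded in the report); metrics are computed per repeat from the
    pooled out-of-fold predictions.
    """
    labels = labels.aligned_to(D.graph_ids)
    y = np.asarray(labels.labels)
    classes = labels.classes
    if len(classes) < 2:
        raise ValueError("classification needs at least two classes")
    smallest = min(int((y == c).sum()) for c in classes)
    if smallest < folds:
        raise ValueError(
            f"smallest class has {smallest} members, fewer than "
            f"folds={folds}; reduce the number of folds"
        )
    X = np.asarray(D.matrix, dtype=float)
    seeds = [seed + r for r in range(repeats)]
    per_repeat = [
        _cv_once(X, y, folds, s, len(classes), C) for s in seeds
    ]
    return EvaluationReport(per_repeat=per_repeat, seeds=seeds)


def evaluate_holdout(
    D: DistanceMatrix,
    labels: LabeledCollection,
    seed: int = 0,
    C: float = 1.0,
) -> EvaluationReport:
    """Single fit on the flagged training graphs, scored on the test
    graphs. Features are distances to training graphs only, so a test
    sample's representation never depends on other held-out samples."""
    labels = labels.aligned_to(D.graph_ids)
    if labels.split is None:
        raise ValueError("labels must carry train/test split flags")
    split = np.asarray(labels.split)
    train = split == "train"
    test = split == "test"
    if not test.any():
        raise ValueError("test set is empty")
    if not train.any():
        raise ValueError("training set is empty")
    y = np.asarray(labels.labels)
    X = np.asarray(D.matrix, dtype=float)[:, train]  # distances to train graphs
    n_classes = len(set(y[train]))
    if n_classes < 2:
        raise ValueError("training set needs at least two classes")
    y_pred = _fit_predict(X[train], y[train], X[test], n_classes, C)
    report = EvaluationReport(per_repeat=[_score(y[test], y_pred)], seeds=[seed])
    return report


def evaluate_embeddings(
    X: np.ndarray,
    labels: LabeledCollection,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> EvaluationReport:
    """One pass of stratified k-fold CV on per-graph feature vectors
    (e.g. whole-graph embeddings produced by an external method)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(labels.graph_ids):
        raise ValueError(
            f"feature rows ({X.shape[0]}) do not match labels "
            f"({len(labels.graph_ids)})"
        )
    y = np.asarray(labels.labels)
    classes = labels.classes
    if len(classes) < 2:
        raise ValueError("classification needs at least two classes")
    smallest = min(int((y == c).sum()) for c in classes)
    if smallest < folds:
        raise ValueError(
            f"smallest class has {smallest} members, fewer than "
            f"folds={folds}; reduce the number of folds"
        )
    result = _cv_once(X, y, folds, seed, len(classes), C)
    return EvaluationReport(per_repeat=[result], seeds=[seed])
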