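"""RBF-SVM classification with grid search over (C, gamma).

The penalty C and kernel width gamma are chosen by exhaustive search over
log-spaced grids (default {1e-3 .. 1e3} each), scoring each pair by mean
stratified k-fold cross-validation accuracy (default five folds) with a
seeded, hence reproducible, fold assignment.  Ties prefer the smaller C,
then the smaller gamma.  Features are standardized inside each training
fold by default because log-variance features are unbounded and RBF
kernels are scale-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_fixture import DEFAULT_GRID

__all__ = ["TrainedClassifier", "make_svm", "grid_search_cv", "evaluate"]


@dataclass
class TrainedClassifier:
    C: float
    g: float
    cv_accuracy: float
    folds: int
    model: Pipeline = field(repr=False, default=None)
    n_fold_fits: int = 0

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict(features)


def make_svm(C: float, g: float, standardize: bool = True) -> Pipeline:
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(C=C, gamma=g, kernel="rbf")))
    return Pipeline(steps)


def grid_search_cv(
    features: np.ndarray,
    labels: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_GRID,
    g_grid: Sequence[float] = DEFAULT_GRID,
    k: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> TrainedClassifier:
    """Pick (C, gamma) by mean stratified k-fold CV accuracy; refit on all data."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {len(classes)}")
    if counts.min() < k:
        raise ValueError(
            f"class {classes[np.argmin(counts)]} has only {counts.min()} trials, "
            f"fewer than k={k} folds; reduce k"
        )

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(features, labels))

    best = None  # (accuracy, C, g); strict improvement keeps smallest C then g
    n_fits = 0
    for C in sorted(C_grid):
        for g in sorted(g_grid):
            accs = []
            for train_idx, test_idx in folds:
                clf = make_svm(C, g, standardize)
                clf.fit(features[train_idx], labels[train_idx])
                accs.append(clf.score(features[test_idx], labels[test_idx]))
                n_fits += 1
            mean_acc = float(np.mean(accs))
            if best is None or mean_acc > best[0]:
                best = (mean_acc, C, g)

    cv_accuracy, C, g = best
    final = make_svm(C, g, standardize)
    final.fit(features, labels)
    return TrainedClassifier(
        C=C, g=g, cv_accuracy=cv_accuracy, folds=k, model=final, n_fold_fits=n_fits
    )


def evaluate(clf: TrainedClassifier, features: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of correct predictions on a labeled feature set."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValueError("features must be a non-empty 2-D matrix")
    if features.shape[0] != labels.shape[0]:
        raise ValueError("feature and label counts differ")
    pred = clf.predict(features)
    return float(np.mean(pred == labels))
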