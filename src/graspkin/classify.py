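"""Per-epoch object-size decoding with a soft-margin RBF-kernel SVM.

At each of the ten epochs the 12-feature slice is classified with an SVM
using the Gaussian kernel K(xi, xj) = exp(-gamma ||xi - xj||^2).  The two
hyperparameters — the misclassification penalty C and the kernel width
gamma — are chosen by exhaustive grid search over log2-spaced candidates,
scored by the same stratified ten-fold cross-validation whose mean held-out
accuracy is reported (libsvm-guide practice; a nested mode re-runs the grid
search inside every outer training split for a selection-bias-free
estimate).  Per-feature z-scaling is fit on training folds only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import EpochFeatureMatrix

__all__ = ["SVMSettings", "AccuracyCurve", "cv_accuracy", "grid_search",
           "accuracy_over_time", "DEFAULT_C_GRID", "DEFAULT_GAMMA_GRID"]

DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** k for k in range(-15, 4, 2))


@dataclass(frozen=True)
class SVMSettings:
    """RBF-SVM hyperparameters, candidate grids and fold construction."""

    C: float = 1.0
    gamma: float = 0.1
    c_grid: tuple[float, ...] = field(default_factory=lambda: DEFAULT_C_GRID)
    gamma_grid: tuple[float, ...] = field(default_factory=lambda: DEFAULT_GAMMA_GRID)
    n_folds: int = 10
    fold_seed: int = 0
    scale: bool = True     # z-score features, fit on training folds only
    nested: bool = False   # leakage-free outer/inner CV for accuracy_over_time

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be > 0")
        if any(v <= 0 for v in self.c_grid) or any(v <= 0 for v in self.gamma_grid):
            raise ValueError("all grid values must be > 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class AccuracyCurve:
    """Cross-validated accuracy (%) per epoch with selected hyperparameters."""

    epochs: np.ndarray                 # (10,)
    accuracy_pct: np.ndarray           # (10,)
    C: np.ndarray                      # (10,)
    gamma: np.ndarray                  # (10,)
    fold_accuracies: np.ndarray        # (10, n_folds), percent

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({
            "epoch_pct": self.epochs.astype(int),
            "accuracy_pct": self.accuracy_pct,
            "C": self.C,
            "gamma": self.gamma,
        })
        for k in range(self.fold_accuracies.shape[1]):
            df[f"fold{k + 1}"] = self.fold_accuracies[:, k]
        return df


def _make_folds(y: np.ndarray, settings: SVMSettings) -> tuple[StratifiedKFold, int]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    n_folds = settings.n_folds
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("need at least 2 trials of each class")
    if min_count < n_folds:
        warnings.warn(f"smallest class has {min_count} trials; refolding with "
                      f"{min_count} folds instead of {n_folds}", stacklevel=3)
        n_folds = min_count
    return StratifiedKFold(n_splits=n_folds, shuffle=True,
                           random_state=settings.fold_seed), n_folds


def cv_accuracy(X: np.ndarray, y: np.ndarray, settings: SVMSettings = SVMSettings(),
                C: float | None = None, gamma: float | None = None,
                ) -> tuple[float, np.ndarray]:
    """Mean held-out accuracy (%) of the RBF SVM under stratified k-fold CV.

    Scaling parameters are re-fit on every training split.  Returns the mean
    and the per-fold accuracies (%).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    C = settings.C if C is None else C
    gamma = settings.gamma if gamma is None else gamma
    skf, n_folds = _make_folds(y, settings)
    fold_acc = np.empty(n_folds)
    for k, (train, test) in enumerate(skf.split(X, y)):
        Xtr, Xte = X[train], X[test]
        if settings.scale:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        clf = SVC(C=C, gamma=gamma, kernel="rbf").fit(Xtr, y[train])
        fold_acc[k] = 100.0 * np.mean(clf.predict(Xte) == y[test])
    return float(fold_acc.mean()), fold_acc


def grid_search(X: np.ndarray, y: np.ndarray, settings: SVMSettings = SVMSettings(),
                ) -> tuple[float, float, float, np.ndarray]:
    """Exhaustively evaluate the (C, gamma) grid by cross-validated accuracy.

    Ties break deterministically toward the smallest C, then the smallest
    gamma.  Returns (C, gamma, best accuracy %, per-fold accuracies).
    """
    if not settings.c_grid or not settings.gamma_grid:
        raise ValueError("hyperparameter grid must be non-empty")
    best = None
    for C in sorted(settings.c_grid):
        for gamma in sorted(settings.gamma_grid):
            acc, folds = cv_accuracy(X, y, settings, C=C, gamma=gamma)
            if best is None or acc > best[2]:
                best = (C, gamma, acc, folds)
    assert best is not None
    return best


def accuracy_over_time(matrix: EpochFeatureMatrix,
                       settings: SVMSettings = SVMSettings()) -> AccuracyCurve:
    """Grid-searched cross-validated accuracy at every epoch independently.

    All trials are pooled across participants; each epoch's 12-feature slice
    gets its own hyperparameter search.  With ``settings.nested`` the grid
    search runs inside every outer training split and the reported accuracy
    is the outer held-out accuracy.
    """
    y = matrix.labels
    n_e = len(matrix.epochs)
    acc = np.empty(n_e)
    Cs = np.empty(n_e)
    gammas = np.empty(n_e)
    folds_out = None
    for i in range(n_e):
        X = matrix.values[:, i, :]
        if settings.nested:
            skf, n_folds = _make_folds(y, settings)
            fold_acc = np.empty(n_folds)
            inner = replace(settings, fold_seed=settings.fold_seed + 1)
            sel_C = sel_g = None
            for k, (train, test) in enumerate(skf.split(X, y)):
                C_k, g_k, _, _ = grid_search(X[train], y[train], inner)
                a_k, _ = _holdout_accuracy(X[train], y[train], X[test], y[test],
                                           settings, C_k, g_k)
                fold_acc[k] = a_k
                sel_C, sel_g = C_k, g_k
            acc[i], folds = fold_acc.mean(), fold_acc
            Cs[i], gammas[i] = sel_C, sel_g
        else:
            Cs[i], gammas[i], acc[i], folds = grid_search(X, y, settings)
        if folds_out is None:
            folds_out = np.empty((n_e, len(folds)))
        folds_out[i] = folds
    return AccuracyCurve(epochs=matrix.epochs.copy(), accuracy_pct=acc,
                         C=Cs, gamma=gammas, fold_accuracies=folds_out)


def _holdout_accuracy(Xtr, ytr, Xte, yte, settings, C, gamma):
    if settings.scale:
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
    clf = SVC(C=C, gamma=gamma, kernel="rbf").fit(Xtr, ytr)
    return 100.0 * np.mean(clf.predict(Xte) == yte), clf
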