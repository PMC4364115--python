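"""Fisher-criterion feature discriminability and epoch-wise paired contrasts.

The F-score of a single feature is the classic Fisher criterion

    F = (mu_plus - mu_minus)^2 / (var_plus + var_minus)

with unbiased sample variances.  For a feature vector the F-group score is

    F = ||mu_plus - mu_minus||^2 / (tr(Sigma_plus) + tr(Sigma_minus))

i.e. between-class separation over total within-class scatter.  A variant
with a *difference* of traces in the denominator is retained as
``mode='as_printed'`` for audits; that denominator can be negative or zero,
which is why the sum is the default.  Features are z-standardized (pooled
over both classes) before the group score so that millimetres, mm/s and
unitless components contribute comparably.

Epoch-wise contrasts follow the repeated-measures post hoc convention:
trials are averaged within participant and object size, a paired t test is
run across participants per feature and epoch, and p-values are
Bonferroni-corrected within each feature's ten-epoch family.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EpochFeatureMatrix, GraspkinError

__all__ = [
    "fscore_single", "fscore_group", "fscore_over_time", "epochwise_contrasts",
    "FScoreTable",
]


class UndefinedScoreError(GraspkinError):
    """The as-printed F-group denominator vanished."""


def fscore_single(values_plus: np.ndarray, values_minus: np.ndarray) -> float:
    """Fisher criterion for one feature: squared mean difference over the sum
    of unbiased class variances.

    Degenerate cases: both variances zero with equal means -> 0; both zero
    with different means -> +inf with a warning.
    """
    a = np.asarray(values_plus, float)
    b = np.asarray(values_minus, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 values")
    num = (a.mean() - b.mean()) ** 2
    den = a.var(ddof=1) + b.var(ddof=1)
    if den == 0.0:
        if num == 0.0:
            return 0.0
        warnings.warn("zero within-class variance with distinct means; "
                      "F-score is infinite", stacklevel=2)
        return float("inf")
    return float(num / den)


def fscore_group(X_plus: np.ndarray, X_minus: np.ndarray, mode: str = "sum") -> float:
    """F-score of a feature vector: ||mean difference||^2 over the combined
    trace of the class covariance matrices (``mode='sum'``, default) or over
    their difference (``mode='as_printed'``)."""
    Xp = np.atleast_2d(np.asarray(X_plus, float))
    Xm = np.atleast_2d(np.asarray(X_minus, float))
    if Xp.shape[0] < 2 or Xm.shape[0] < 2:
        raise ValueError("each class needs at least 2 trials")
    num = float(np.sum((Xp.mean(axis=0) - Xm.mean(axis=0)) ** 2))
    tr_p = float(np.trace(np.cov(Xp, rowvar=False, ddof=1).reshape(Xp.shape[1], -1)))
    tr_m = float(np.trace(np.cov(Xm, rowvar=False, ddof=1).reshape(Xm.shape[1], -1)))
    if mode == "sum":
        den = tr_p + tr_m
        if den == 0.0:
            return 0.0 if num == 0.0 else float("inf")
        return num / den
    if mode == "as_printed":
        den = tr_p - tr_m
        if abs(den) < 1e-12:
            raise UndefinedScoreError(
                "as_printed F-group denominator tr(S+) - tr(S-) is ~0")
        if den < 0:
            warnings.warn("as_printed F-group denominator is negative; the "
                          "score is not a valid scatter ratio", stacklevel=2)
        return num / den
    raise ValueError(f"unknown mode {mode!r}")


class FScoreTable:
    """Per-feature-per-epoch F-scores plus a per-epoch F-group score."""

    def __init__(self, fscores: np.ndarray, fgroup: np.ndarray,
                 feature_names: tuple[str, ...], epochs: np.ndarray,
                 denominator_mode: str = "sum") -> None:
        self.fscores = np.asarray(fscores, float)        # (10, 12)
        self.fgroup = np.asarray(fgroup, float)          # (10,)
        self.feature_names = feature_names
        self.epochs = np.asarray(epochs)
        self.denominator_mode = denominator_mode

    def feature_scores(self, feature: str) -> np.ndarray:
        return self.fscores[:, self.feature_names.index(feature)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (feature, epoch_pct, fscore) with the F-group score as
        the pseudo-feature ``fgroup`` — ready for heat-map rendering."""
        rows = []
        for i, e in enumerate(self.epochs):
            for j, f in enumerate(self.feature_names):
                rows.append((f, int(e), self.fscores[i, j]))
            rows.append(("fgroup", int(e), self.fgroup[i]))
        return pd.DataFrame(rows, columns=["feature", "epoch_pct", "fscore"])


def fscore_over_time(matrix: EpochFeatureMatrix, mode: str = "sum",
                     standardize: bool = True) -> FScoreTable:
    """Single-feature F-score for every feature at every epoch, plus the
    per-epoch F-group score over the (optionally z-standardized) 12-vector.

    The class labelled 'large' is taken as the '+' class.
    """
    plus = matrix.class_mask("large")
    minus = matrix.class_mask("small")
    for e in matrix.epochs:
        if plus.sum() < 2 or minus.sum() < 2:
            raise ValueError(f"epoch {e}%: both classes must be present")
    n_e = len(matrix.epochs)
    n_f = len(matrix.feature_names)
    fscores = np.empty((n_e, n_f))
    fgroup = np.empty(n_e)
    for i in range(n_e):
        X = matrix.values[:, i, :]
        for j in range(n_f):
            fscores[i, j] = fscore_single(X[plus, j], X[minus, j])
        Z = X
        if standardize:
            # pooled *within-class* SD: the classic pooled estimator; using
            # the overall SD instead would let large separations deflate
            # their own scale and cap the score
            mu = X.mean(axis=0)
            sp = np.sqrt(0.5 * (X[plus].var(axis=0, ddof=1)
                                + X[minus].var(axis=0, ddof=1)))
            sp[sp == 0] = 1.0
            Z = (X - mu) / sp
        fgroup[i] = fscore_group(Z[plus], Z[minus], mode=mode)
    return FScoreTable(fscores, fgroup, matrix.feature_names, matrix.epochs,
                       denominator_mode=mode)


def epochwise_contrasts(matrix: EpochFeatureMatrix, alpha: float = 0.05,
                        family: str = "per_feature") -> pd.DataFrame:
    """Paired large-vs-small contrasts per feature and epoch.

    Trials are first averaged within participant and object size; a paired t
    test across participants is then run per (feature, epoch).  Bonferroni
    correction uses the feature's ten-epoch family by default
    (``family='all'`` corrects over all feature-epoch tests instead).
    Participants missing one object size are dropped with a warning; zero
    variance of the paired differences falls back to an exact sign test
    (flagged in the ``zero_variance`` column).
    """
    pids = np.unique(matrix.participant_ids)
    keep = []
    for pid in pids:
        sel = matrix.participant_ids == pid
        if (matrix.labels[sel] == "large").any() and (matrix.labels[sel] == "small").any():
            keep.append(pid)
        else:
            warnings.warn(f"participant {pid} lacks one object size; dropped",
                          stacklevel=2)
    if len(keep) < 3:
        raise ValueError("need >= 3 participants with both object sizes")
    n_e = len(matrix.epochs)
    n_f = len(matrix.feature_names)
    large = np.empty((len(keep), n_e, n_f))
    small = np.empty_like(large)
    for k, pid in enumerate(keep):
        sel = matrix.participant_ids == pid
        large[k] = matrix.values[sel & matrix.class_mask("large")].mean(axis=0)
        small[k] = matrix.values[sel & matrix.class_mask("small")].mean(axis=0)
    diffs = large - small                         # (n_participants, 10, 12)
    n_family = n_e if family == "per_feature" else n_e * n_f
    rows = []
    for j in range(n_f):
        for i in range(n_e):
            d = diffs[:, i, j]
            zero_var = bool(np.allclose(d, d[0]))
            if zero_var:
                if np.allclose(d, 0.0):
                    t_stat, p_raw = 0.0, 1.0
                else:
                    # constant non-zero differences: exact sign test
                    n_pos = int(np.sum(d > 0))
                    p_raw = stats.binomtest(n_pos, len(d), 0.5).pvalue
                    t_stat = float("inf") if d[0] > 0 else float("-inf")
            else:
                t_stat, p_raw = stats.ttest_rel(large[:, i, j], small[:, i, j])
            p_adj = min(1.0, float(p_raw) * n_family)
            rows.append((matrix.feature_names[j], int(matrix.epochs[i]),
                         float(d.mean()), float(t_stat), float(p_raw), p_adj,
                         p_adj < alpha, zero_var))
    return pd.DataFrame(rows, columns=[
        "feature", "epoch_pct", "mean_diff", "t", "p_raw", "p_adj",
        "significant", "zero_variance"])
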