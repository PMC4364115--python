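"""Per-epoch RBF-SVM decoding: CV accuracy, grid search, reproducibility."""
import dataclasses

import numpy as np
import pytest

from graspkin.classify import SVMSettings, accuracy_over_time, cv_accuracy, grid_search
from sklearn.preprocessing import StandardScaler

from conftest import make_matrix

SMALL = SVMSettings(c_grid=(0.5, 8.0), gamma_grid=(2.0**-7, 2.0**-3),
                    n_folds=5, fold_seed=0)


def _two_blobs(n=60, sep=10.0, sd=0.1, d=1, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-sep, sd, (n // 2, d)), rng.normal(sep, sd, (n // 2, d))])
    y = np.array(["small"] * (n // 2) + ["large"] * (n // 2))
    return X, y


def test_settings_validation():
    with pytest.raises(ValueError):
        SVMSettings(C=-1)
    with pytest.raises(ValueError):
        SVMSettings(gamma=0)
    with pytest.raises(ValueError):
        SVMSettings(n_folds=1)
    with pytest.raises(ValueError):
        SVMSettings(c_grid=(1.0, -2.0))


def test_separable_classes_near_perfect_accuracy():
    X, y = _two_blobs()
    acc, folds = cv_accuracy(X, y, SMALL)
    assert acc >= 99.0
    assert len(folds) == 5


def test_permuted_labels_near_chance():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 12))
    y = np.array(["small", "large"] * 100)
    acc, _ = cv_accuracy(X, rng.permutation(y), SMALL)
    assert 38.0 <= acc <= 62.0


def test_contradictory_duplicates_score_exactly_chance():
    # every point duplicated with both labels is maximally ambiguous: any
    # decision rule scores exactly 50% on such an evaluation set.  (Under
    # k-fold CV the same construction scores *below* chance, because each
    # test point's twin sits in the training set with the opposite label.)
    from sklearn.svm import SVC

    rng = np.random.default_rng(2)
    Xtr, ytr = _two_blobs(n=60, sep=1.0, sd=1.0, d=4)
    clf = SVC(C=1.0, gamma=0.1).fit(Xtr, ytr)
    X = rng.normal(size=(150, 4))
    X2 = np.vstack([X, X])
    y2 = np.array(["small"] * 150 + ["large"] * 150)
    acc = 100.0 * np.mean(clf.predict(X2) == y2)
    assert acc == pytest.approx(50.0)


def test_label_symmetry():
    X, y = _two_blobs(n=80, sep=1.0, sd=1.0)
    swapped = np.where(y == "small", "large", "small")
    acc1, _ = cv_accuracy(X, y, SMALL)
    acc2, _ = cv_accuracy(X, swapped, SMALL)
    assert acc1 == pytest.approx(acc2, abs=1e-9)


def test_cv_accuracy_reproducible():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(100, 6))
    y = np.array(["small", "large"] * 50)
    assert cv_accuracy(X, y, SMALL)[0] == cv_accuracy(X, y, SMALL)[0]


def test_refold_warning_when_class_too_small():
    X, y = _two_blobs(n=8)
    with pytest.warns(UserWarning, match="refolding"):
        acc, folds = cv_accuracy(X, y, dataclasses.replace(SMALL, n_folds=10))
    assert len(folds) == 4


def test_single_class_or_tiny_class_errors():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError, match="both classes"):
        cv_accuracy(X, np.array(["small"] * 10), SMALL)
    y = np.array(["small"] * 9 + ["large"])
    with pytest.raises(ValueError, match="at least 2 trials"):
        cv_accuracy(X, y, SMALL)


def test_grid_search_single_point_and_empty():
    X, y = _two_blobs()
    one = dataclasses.replace(SMALL, c_grid=(2.0,), gamma_grid=(0.25,))
    C, gamma, acc, _ = grid_search(X, y, one)
    assert (C, gamma) == (2.0, 0.25)
    with pytest.raises(ValueError, match="non-empty"):
        grid_search(X, y, dataclasses.replace(SMALL, c_grid=()))


def test_grid_search_achieves_grid_maximum_with_smallest_tie():
    X, y = _two_blobs(n=40, sep=2.0, sd=1.5, d=3, seed=5)
    C, gamma, best, _ = grid_search(X, y, SMALL)
    evals = {(c, g): cv_accuracy(X, y, SMALL, C=c, gamma=g)[0]
             for c in SMALL.c_grid for g in SMALL.gamma_grid}
    assert best == max(evals.values())
    winners = sorted(k for k, v in evals.items() if v == best)
    assert (C, gamma) == winners[0]


def test_grid_search_tiebreak_on_degenerate_data():
    # all-zero features: every hyperparameter pair ties -> smallest returned
    X = np.zeros((40, 3))
    y = np.array(["small", "large"] * 20)
    C, gamma, _, _ = grid_search(X, y, SMALL)
    assert (C, gamma) == (min(SMALL.c_grid), min(SMALL.gamma_grid))


def test_training_only_scaling_never_beats_leaky_scaling():
    # scaling fit on the full data leaks test-fold statistics; on average it
    # can only help, so the compliant run must not exceed the leaky one
    comp, leaky = [], []
    for seed in range(10):
        X, y = _two_blobs(n=20, sep=0.6, sd=1.0, d=4, seed=seed)
        s = dataclasses.replace(SMALL, n_folds=4, fold_seed=seed)
        comp.append(cv_accuracy(X, y, s)[0])
        Xs = StandardScaler().fit_transform(X)
        leaky.append(cv_accuracy(Xs, y, dataclasses.replace(s, scale=False))[0])
    assert np.mean(leaky) >= np.mean(comp) - 2.0


def _monotone_matrix(n=120, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.normal(0, 1, (n, 10, 12))
    labels = np.array(["small", "large"] * (n // 2))
    effect = np.linspace(0.2, 2.2, 10)            # effect grows with epoch
    values[labels == "large"] += effect[None, :, None] * 0.4
    return make_matrix(values, labels=labels)


def test_accuracy_over_time_monotone_effect_gives_rising_curve():
    m = _monotone_matrix()
    curve = accuracy_over_time(m, SMALL)
    assert curve.accuracy_pct.shape == (10,)
    assert curve.accuracy_pct[-1] > curve.accuracy_pct[0]
    # broadly non-decreasing up to Monte-Carlo error
    assert np.all(np.diff(curve.accuracy_pct) > -8.0)


def test_accuracy_over_time_reproducible_and_null_near_chance():
    rng = np.random.default_rng(8)
    m = make_matrix(rng.normal(0, 1, (160, 10, 12)),
                    labels=np.array(["small", "large"] * 80))
    c1 = accuracy_over_time(m, SMALL)
    c2 = accuracy_over_time(m, SMALL)
    assert np.array_equal(c1.accuracy_pct, c2.accuracy_pct)
    assert np.array_equal(c1.C, c2.C) and np.array_equal(c1.gamma, c2.gamma)
    assert np.all(c1.accuracy_pct < 70.0)


def test_nested_mode_runs_and_stays_honest_on_null_data():
    rng = np.random.default_rng(12)
    m = make_matrix(rng.normal(0, 1, (80, 10, 12)),
                    labels=np.array(["small", "large"] * 40))
    nested = dataclasses.replace(SMALL, n_folds=4, nested=True)
    curve = accuracy_over_time(m, nested)
    assert np.all((20.0 <= curve.accuracy_pct) & (curve.accuracy_pct <= 80.0))
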