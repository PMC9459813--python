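import warnings

import numpy as np
import pandas as pd
import pytest

from stairpower.classify import (
    LabeledDataset,
    balance_classes,
    build_labeled_dataset,
    compute_feature_importances,
    drop_correlated_features,
    select_features_rfecv,
    train_and_evaluate,
)
from stairpower.synthetic import SyntheticConfig, simulate_labeled_dataset

TINY_GRIDS = {
    "knn": {"clf__n_neighbors": [5]},
    "random_forest": {"clf__n_estimators": [50]},
    "logistic_regression": {"clf__C": [1.0]},
}


def toy_dataset(n_subjects=6, per_subject=20, n_features=5, informative=1,
                margin=3.0, seed=0, y=None):
    """Gaussian feature dataset with known informative dimensions."""
    rng = np.random.default_rng(seed)
    n = n_subjects * per_subject
    if y is None:
        y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, n_features))
    for j in range(informative):
        X[:, j] += margin * y
    meta = pd.DataFrame(
        {
            "subject": np.repeat([f"S{i}" for i in range(n_subjects)], per_subject),
            "visit": "V1",
            "task": "t",
        }
    )
    cols = [f"f{j}" for j in range(n_features)]
    return LabeledDataset(X=pd.DataFrame(X, columns=cols), y=y, meta=meta)


class TestBalanceClasses:
    def _ds(self, pos, neg, subjects=1):
        n = pos + neg
        y = np.r_[np.ones(pos, int), np.zeros(neg, int)]
        X = pd.DataFrame({"f0": np.arange(n, dtype=float)})
        meta = pd.DataFrame({"subject": ["S0"] * n, "visit": ["V1"] * n,
                             "task": ["t"] * n})
        return LabeledDataset(X=X, y=y, meta=meta)

    def test_excess_negatives_subsampled(self):
        out = balance_classes(self._ds(10, 25), seed=0)
        assert out.n == 20 and out.y.sum() == 10

    def test_already_balanced_is_identity(self):
        ds = self._ds(10, 10)
        out = balance_classes(ds, seed=0)
        assert out.n == 20
        np.testing.assert_array_equal(out.X["f0"], ds.X["f0"])

    def test_deterministic_given_seed(self):
        a = balance_classes(self._ds(10, 25), seed=42)
        b = balance_classes(self._ds(10, 25), seed=42)
        np.testing.assert_array_equal(a.X["f0"], b.X["f0"])

    def test_insufficient_negatives_drops_stratum_with_warning(self):
        ds = self._ds(10, 5)
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ValueError, match="no stratum"):
                balance_classes(ds, seed=0)


class TestDropCorrelatedFeatures:
    def _ds_from_X(self, X):
        n = len(X)
        meta = pd.DataFrame({"subject": ["S0"] * n, "visit": "V1", "task": "t"})
        return LabeledDataset(X=X, y=np.zeros(n, int), meta=meta)

    def test_perfect_collinearity_dropped(self, rng):
        a = rng.standard_normal(200)
        c = rng.standard_normal(200)
        X = pd.DataFrame({"A": a, "B": 2 * a + 1e-9 * c, "C": c})
        out = drop_correlated_features(self._ds_from_X(X))
        assert list(out.X.columns) == ["A", "C"]

    def test_orthogonal_features_untouched(self, rng):
        X = pd.DataFrame(rng.standard_normal((300, 4)), columns=list("ABCD"))
        out = drop_correlated_features(self._ds_from_X(X))
        assert list(out.X.columns) == list("ABCD")

    def test_correlation_chain_keeps_endpoints(self, rng):
        # construct A~B (r=.93), B~C (r=.93), A~C (r=.865 <= .90) exactly
        # from an orthonormalized zero-mean basis
        M = rng.standard_normal((400, 3))
        M -= M.mean(axis=0)
        q, _ = np.linalg.qr(M)
        u, v, w = q.T
        r = 0.93
        A = u
        B = r * u + np.sqrt(1 - r**2) * v
        rc_a = r * r  # implied corr(A, C) when C = r*B + orth
        beta = (r - rc_a * r) / np.sqrt(1 - r**2)
        C = rc_a * u + beta * v + np.sqrt(max(0.0, 1 - rc_a**2 - beta**2)) * w
        # verify the premise with a brute-force pairwise r
        cor = lambda x, y: float(np.corrcoef(x, y)[0, 1])
        assert cor(A, B) > 0.90 and cor(B, C) > 0.90 and cor(A, C) <= 0.90
        out = drop_correlated_features(
            self._ds_from_X(pd.DataFrame({"A": A, "B": B, "C": C}))
        )
        assert list(out.X.columns) == ["A", "C"]


class TestRfecv:
    def test_informative_features_retained_among_noise(self):
        ds = toy_dataset(n_subjects=8, per_subject=25, n_features=22,
                         informative=2, margin=3.0, seed=1)
        selected = select_features_rfecv(ds, seed=0)
        assert {"f0", "f1"} <= set(selected)

    def test_deterministic_given_seed(self):
        ds = toy_dataset(n_subjects=6, per_subject=15, n_features=8, seed=2,
                         informative=1)
        assert select_features_rfecv(ds, seed=3) == select_features_rfecv(ds, seed=3)

    def test_single_class_rejected(self):
        ds = toy_dataset(seed=3)
        ds.y[:] = 1
        with pytest.raises(ValueError, match="both classes"):
            select_features_rfecv(ds, seed=0)


class TestTrainAndEvaluate:
    def test_perfect_single_feature_gives_perfect_metrics(self):
        ds = toy_dataset(n_subjects=6, per_subject=20, n_features=3,
                         informative=1, margin=8.0, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = train_and_evaluate(ds, seed=0, grids=TINY_GRIDS)
        for model, per in rep.metrics.items():
            assert per["sensitivity"]["mean"] == pytest.approx(1.0), model
            assert per["specificity"]["mean"] == pytest.approx(1.0), model

    def test_fold_subject_partitions_are_disjoint(self):
        ds = toy_dataset(n_subjects=6, per_subject=10, seed=5, margin=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = train_and_evaluate(ds, seed=0, grids=TINY_GRIDS)
        assert rep.n_folds == 6  # reduced from 10 to the subject count
        for fold in rep.fold_subjects:
            assert not set(fold["train"]) & set(fold["test"])

    def test_importances_normalized_and_informative_ranks_first(self):
        ds = toy_dataset(n_subjects=6, per_subject=25, n_features=10,
                         informative=1, margin=4.0, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = train_and_evaluate(ds, seed=0, grids=TINY_GRIDS)
        assert rep.importances.sum() == pytest.approx(1.0, abs=1e-9)
        ranked = compute_feature_importances(rep, top_k=3)
        assert ranked[0][0] == "f0"


def test_build_labeled_dataset_labels_and_shapes():
    windows = simulate_labeled_dataset(SyntheticConfig(), 3, 1, seed=21)
    ds = build_labeled_dataset(windows, "stairs-vs-gait", "accel")
    assert ds.X.shape[1] == 76
    assert set(np.unique(ds.y)) == {0, 1}
    ds2 = build_labeled_dataset(windows, "ascent-vs-descent", "gyro")
    assert ds2.X.shape[1] == 72
    assert ds2.n < ds.n  # gait windows excluded
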