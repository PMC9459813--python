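"""Binary activity classification from windowed IMU features.

Implements the training protocol for the two classification problems of
interest -- stair walking vs. level gait, and stair ascent vs. descent --
for accelerometer-only, gyroscope-only and combined feature sets:

1. class balancing (1:1) by subsampling negatives within each
   (subject, visit) stratum,
2. removal of features with pairwise |Pearson r| > 0.90 (greedy scan in
   canonical feature order),
3. recursive feature elimination with group-aware cross-validated
   scoring (random-forest ranker),
4. outer 10-fold cross-validation *grouped by subject* (no subject ever
   contributes to both the training and test side of a fold), with a
   hyperparameter grid search nested inside each training fold,
5. four models: k-nearest neighbors, random forest, logistic
   regression, and a soft-voting ensemble of the three; metrics are
   accuracy, sensitivity (recall on the positive class) and
   specificity, reported as mean (std) across folds,
6. impurity-based feature importances from the random-forest folds,
   normalized to sum to one.

Features are z-scored inside each fold (fit on train, applied to test);
this matters for knn and logistic regression and is harmless for trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier, VotingClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import extract_features, feature_names
from .segmentation import SegmentWindow

__all__ = [
    "LabeledDataset",
    "ModelReport",
    "DEFAULT_GRIDS",
    "CLASSIFICATION_TASKS",
    "build_labeled_dataset",
    "balance_classes",
    "drop_correlated_features",
    "select_features_rfecv",
    "train_and_evaluate",
    "holdout_evaluate",
    "compute_feature_importances",
    "run_classification_experiment",
]

#: task name -> (positive labels, negative labels)
CLASSIFICATION_TASKS = {
    "stairs-vs-gait": ({"ascent", "descent"}, {"gait"}),
    "ascent-vs-descent": ({"ascent"}, {"descent"}),
}

#: Hyperparameter grids searched inside each training fold.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"clf__n_neighbors": [3, 5, 7, 11]},
    "random_forest": {
        "clf__n_estimators": [100, 300],
        "clf__max_depth": [None, 10],
    },
    "logistic_regression": {"clf__C": [0.1, 1.0, 10.0]},
}

_METRICS = ("accuracy", "sensitivity", "specificity")
MODEL_NAMES = ("knn", "random_forest", "logistic_regression", "voting_ensemble")


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels and subject/visit/task provenance."""

    X: pd.DataFrame  # one row per window, canonical feature columns
    y: np.ndarray  # 1 = positive class, 0 = negative
    meta: pd.DataFrame  # columns: subject, visit, task
    sensor_set: str = "both"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != self.y.size or len(self.meta) != self.y.size:
            raise ValueError("X, y and meta must have one row per window")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def groups(self) -> np.ndarray:
        return self.meta["subject"].to_numpy()

    @property
    def n(self) -> int:
        return int(self.y.size)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            sensor_set=self.sensor_set,
        )


def build_labeled_dataset(
    windows: Sequence[SegmentWindow],
    task: str = "stairs-vs-gait",
    sensor_set: str = "both",
) -> LabeledDataset:
    """Featurize windows and attach binary labels for a classification task."""
    if task not in CLASSIFICATION_TASKS:
        raise ValueError(f"task must be one of {sorted(CLASSIFICATION_TASKS)}")
    pos, neg = CLASSIFICATION_TASKS[task]
    rows, labels, meta = [], [], []
    for w in windows:
        if w.label not in pos | neg:
            continue
        rows.append(extract_features(w, sensor_set).values)
        labels.append(1 if w.label in pos else 0)
        meta.append(
            {"subject": w.subject_id, "visit": w.visit_id, "task": w.task_id}
        )
    if not rows:
        raise ValueError(f"no windows with labels for task {task!r}")
    X = pd.DataFrame(rows, columns=feature_names(sensor_set))
    return LabeledDataset(
        X=X, y=np.array(labels), meta=pd.DataFrame(meta), sensor_set=sensor_set
    )


def balance_classes(ds: LabeledDataset, seed: int) -> LabeledDataset:
    """Balance classes 1:1 within each (subject, visit) stratum.

    Negatives are subsampled without replacement to the positive count in
    the stratum; strata with too few negatives are dropped with a
    warning.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    strata = ds.meta.groupby(["subject", "visit"], sort=True).indices
    for key in sorted(strata):
        idx = np.sort(np.asarray(strata[key]))
        pos = idx[ds.y[idx] == 1]
        neg = idx[ds.y[idx] == 0]
        if pos.size == 0:
            continue
        if neg.size < pos.size:
            warnings.warn(
                f"stratum {key}: {neg.size} negatives < {pos.size} positives; "
                "stratum dropped",
                stacklevel=2,
            )
            continue
        chosen = neg if neg.size == pos.size else np.sort(
            rng.choice(neg, size=pos.size, replace=False)
        )
        keep.append(np.concatenate([pos, chosen]))
    if not keep:
        raise ValueError("no stratum survived balancing")
    return ds.subset(np.sort(np.concatenate(keep)))


def drop_correlated_features(
    ds: LabeledDataset, threshold: float = 0.90
) -> LabeledDataset:
    """Drop features with |Pearson r| > threshold to any retained feature.

    Greedy scan in canonical feature order: a feature survives only if
    its absolute correlation with every earlier surviving feature is at
    or below the threshold.
    """
    if ds.X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(ds.X.to_numpy(dtype=float), rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns correlate with nothing
    kept: list[int] = []
    for j in range(ds.X.shape[1]):
        if all(corr[j, k] <= threshold for k in kept):
            kept.append(j)
    return replace(ds, X=ds.X.iloc[:, kept].copy())


def select_features_rfecv(
    ds: LabeledDataset,
    seed: int,
    *,
    cv_folds: int = 5,
    step: int = 1,
    min_features: int = 1,
) -> list[str]:
    """Recursive feature elimination with grouped cross-validated scoring.

    A random-forest ranker drops ``step`` feature(s) per iteration; the
    subset maximizing mean grouped-CV accuracy is returned (canonical
    order preserved).
    """
    if ds.X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if np.unique(ds.y).size < 2:
        raise ValueError("both classes must be present")
    n_groups = np.unique(ds.groups).size
    cv = GroupKFold(n_splits=min(cv_folds, n_groups))
    rfecv = RFECV(
        estimator=RandomForestClassifier(n_estimators=100, random_state=seed),
        step=step,
        cv=cv,
        scoring="accuracy",
        min_features_to_select=min_features,
        n_jobs=1,
    )
    rfecv.fit(ds.X.to_numpy(dtype=float), ds.y, groups=ds.groups)
    return [c for c, s in zip(ds.X.columns, rfecv.support_) if s]


@dataclass
class ModelReport:
    """Cross-validated metrics for the four models, plus importances."""

    metrics: dict  # model -> metric -> {"mean": float, "std": float}
    per_fold: dict  # model -> metric -> list[float]
    feature_names: list[str]
    importances: np.ndarray  # normalized impurity importances (RF, fold-avg)
    n_folds: int
    fold_subjects: list[dict]  # per fold: {"train": [...], "test": [...]}

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "per_fold": self.per_fold,
            "feature_names": self.feature_names,
            "importances": self.importances.tolist(),
            "n_folds": self.n_folds,
        }


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return {
        "accuracy": (tp + tn) / max(1, y_true.size),
        "sensitivity": tp / max(1, tp + fn),
        "specificity": tn / max(1, tn + fp),
    }


def _base_pipelines(seed: int) -> dict[str, Pipeline]:
    return {
        "knn": Pipeline(
            [("scale", StandardScaler()), ("clf", KNeighborsClassifier())]
        ),
        "random_forest": Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", RandomForestClassifier(random_state=seed)),
            ]
        ),
        "logistic_regression": Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, random_state=seed)),
            ]
        ),
    }


def train_and_evaluate(
    ds: LabeledDataset,
    seed: int,
    *,
    n_splits: int = 10,
    inner_splits: int = 3,
    grids: dict | None = None,
) -> ModelReport:
    """Grouped outer CV with nested grid search for all four models.

    Outer folds are grouped by subject (warning + reduction if fewer
    subjects than requested folds); the grid search inside each training
    fold is likewise grouped.  The voting ensemble soft-votes the three
    tuned base models.  Asserts, per fold, that no subject appears on
    both sides.
    """
    grids = grids if grids is not None else DEFAULT_GRIDS
    X = ds.X.to_numpy(dtype=float)
    y = ds.y
    groups = ds.groups
    n_subjects = np.unique(groups).size
    if n_subjects < n_splits:
        warnings.warn(
            f"only {n_subjects} subjects; reducing folds from {n_splits}",
            stacklevel=2,
        )
        n_splits = n_subjects
    outer = GroupKFold(n_splits=n_splits)

    per_fold: dict[str, dict[str, list[float]]] = {
        m: {k: [] for k in _METRICS} for m in MODEL_NAMES
    }
    fold_subjects: list[dict] = []
    imp_folds: list[np.ndarray] = []

    for tr, te in outer.split(X, y, groups):
        tr_subj = set(groups[tr])
        te_subj = set(groups[te])
        assert not (tr_subj & te_subj), "subject leakage across a CV fold"
        fold_subjects.append(
            {"train": sorted(tr_subj), "test": sorted(te_subj)}
        )
        inner = GroupKFold(n_splits=min(inner_splits, len(tr_subj)))
        tuned: dict[str, Pipeline] = {}
        for name, pipe in _base_pipelines(seed).items():
            gs = GridSearchCV(
                pipe, grids.get(name, {}), cv=inner, scoring="accuracy", n_jobs=1
            )
            gs.fit(X[tr], y[tr], groups=groups[tr])
            tuned[name] = gs.best_estimator_
        ensemble = VotingClassifier(
            estimators=[(n, clone(p)) for n, p in tuned.items()], voting="soft"
        )
        ensemble.fit(X[tr], y[tr])
        for name, est in {**tuned, "voting_ensemble": ensemble}.items():
            m = _fold_metrics(y[te], est.predict(X[te]))
            for k in _METRICS:
                per_fold[name][k].append(m[k])
        rf = tuned["random_forest"].named_steps["clf"]
        imp_folds.append(rf.feature_importances_)

    metrics = {
        m: {
            k: {
                "mean": float(np.mean(v)),
                "std": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            }
            for k, v in per_fold[m].items()
        }
        for m in MODEL_NAMES
    }
    imp = np.mean(imp_folds, axis=0)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return ModelReport(
        metrics=metrics,
        per_fold={m: dict(v) for m, v in per_fold.items()},
        feature_names=list(ds.X.columns),
        importances=imp,
        n_folds=n_splits,
        fold_subjects=fold_subjects,
    )


def holdout_evaluate(
    ds: LabeledDataset,
    seed: int,
    *,
    test_fraction: float = 0.2,
    inner_splits: int = 3,
    grids: dict | None = None,
) -> dict:
    """One-shot 80/20 evaluation with subjects partitioned by group.

    Alternative to the grouped 10-fold protocol: subjects (not windows)
    are split once into train and test sets, models are tuned on the
    training subjects and scored once on the held-out subjects.
    """
    from sklearn.model_selection import GroupShuffleSplit

    grids = grids if grids is not None else DEFAULT_GRIDS
    X = ds.X.to_numpy(dtype=float)
    y, groups = ds.y, ds.groups
    splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
    tr, te = next(splitter.split(X, y, groups))
    assert not (set(groups[tr]) & set(groups[te])), "subject leakage in holdout"
    inner = GroupKFold(n_splits=min(inner_splits, np.unique(groups[tr]).size))
    tuned: dict[str, Pipeline] = {}
    out: dict[str, dict[str, float]] = {}
    for name, pipe in _base_pipelines(seed).items():
        gs = GridSearchCV(pipe, grids.get(name, {}), cv=inner, scoring="accuracy")
        gs.fit(X[tr], y[tr], groups=groups[tr])
        tuned[name] = gs.best_estimator_
        out[name] = _fold_metrics(y[te], gs.best_estimator_.predict(X[te]))
    ens = VotingClassifier(
        estimators=[(n, clone(p)) for n, p in tuned.items()], voting="soft"
    )
    ens.fit(X[tr], y[tr])
    out["voting_ensemble"] = _fold_metrics(y[te], ens.predict(X[te]))
    return out


def compute_feature_importances(
    report: ModelReport, top_k: int = 20
) -> list[tuple[str, float]]:
    """Fold-averaged, normalized RF importances, descending, top ``top_k``."""
    order = np.argsort(report.importances)[::-1][:top_k]
    return [(report.feature_names[i], float(report.importances[i])) for i in order]


def run_classification_experiment(
    windows: Sequence[SegmentWindow],
    task: str,
    sensor_set: str,
    seed: int,
    *,
    corr_threshold: float = 0.90,
    use_rfecv: bool = True,
    n_splits: int = 10,
) -> ModelReport:
    """Full protocol: featurize, balance, filter, select, train, evaluate."""
    ds = build_labeled_dataset(windows, task=task, sensor_set=sensor_set)
    ds = balance_classes(ds, seed)
    ds = drop_correlated_features(ds, corr_threshold)
    if use_rfecv and ds.X.shape[1] > 2:
        selected = select_features_rfecv(ds, seed)
        ds = replace(ds, X=ds.X.loc[:, selected].copy())
    return train_and_evaluate(ds, seed, n_splits=n_splits)
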