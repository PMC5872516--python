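"""Predictive evaluation of feature subsets by stratified k-fold CV.

Five classifiers — k-nearest neighbours (KNN), a decision tree (DT), a
backpropagation neural network (BPNN, one hidden layer), a random forest
(RF) and a soft-voting ensemble (EC) of the other four — are scored with
stratified 10-fold cross-validation on one-hot-encoded categorical
features.  Reported metrics are AUC, precision, recall and F-score (positive
class = stage-3), averaged over folds with normal-approximation 95%
confidence intervals on the fold means.

Hyperparameters are deliberately plain (KNN k=5, DT with minimum leaf 5,
RF with 500 trees, BPNN with 16 hidden units) and all configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from sklearn.ensemble import RandomForestClassifier, VotingClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = ["CvReport", "MODEL_NAMES", "make_model", "run_cv", "compare_feature_sets"]

MODEL_NAMES = ("KNN", "DT", "BPNN", "RF", "EC")

Z_95 = 1.959963984540054

DEFAULT_PARAMS: dict[str, dict] = {
    "KNN": {"n_neighbors": 5},
    "DT": {"min_samples_leaf": 5},
    "BPNN": {"hidden_layer_sizes": (16,), "max_iter": 600},
    "RF": {"n_estimators": 500},
}


@dataclass
class CvReport:
    """Cross-validated metrics for one (model, feature subset) pair."""

    model: str
    feature_set: str
    k_folds: int
    seed: int
    fold_metrics: dict[str, np.ndarray] = field(default_factory=dict)

    def mean(self, metric: str) -> float:
        return float(np.mean(self.fold_metrics[metric]))

    def ci(self, metric: str) -> tuple[float, float]:
        vals = self.fold_metrics[metric]
        half = Z_95 * float(np.std(vals, ddof=1)) / np.sqrt(len(vals))
        m = float(np.mean(vals))
        return (m - half, m + half)

    @property
    def auc(self) -> float:
        return self.mean("auc")

    @property
    def precision(self) -> float:
        return self.mean("precision")

    @property
    def recall(self) -> float:
        return self.mean("recall")

    @property
    def f_score(self) -> float:
        return self.mean("f_score")


def make_model(name: str, seed: int, params: Mapping[str, dict] | None = None):
    """Instantiate one of the five classifiers with a derived random state."""
    merged = {k: dict(v) for k, v in DEFAULT_PARAMS.items()}
    for k, v in (params or {}).items():
        merged.setdefault(k, {}).update(v)
    if name == "KNN":
        return KNeighborsClassifier(**merged["KNN"])
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **merged["DT"])
    if name == "BPNN":
        return MLPClassifier(random_state=seed, **merged["BPNN"])
    if name == "RF":
        return RandomForestClassifier(random_state=seed, **merged["RF"])
    if name == "EC":
        members = [(n, make_model(n, seed, params)) for n in ("KNN", "DT", "BPNN", "RF")]
        return VotingClassifier(estimators=members, voting="soft")
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def _one_hot(matrix: FeatureMatrix, subset: Sequence[str]) -> np.ndarray:
    """Full one-hot design over each feature's declared alphabet."""
    blocks = []
    for name in subset:
        feat = matrix.feature(name)
        codes = matrix.column(name)
        block = np.zeros((matrix.n, feat.m), dtype=np.float64)
        block[np.arange(matrix.n), codes] = 1.0
        blocks.append(block)
    return np.hstack(blocks)


def run_cv(
    matrix: FeatureMatrix,
    subset: Sequence[str],
    model_name: str,
    k_folds: int = 10,
    seed: int = 0,
    model_params: Mapping[str, dict] | None = None,
    feature_set_name: str | None = None,
) -> CvReport:
    """Stratified k-fold CV of one model on one feature subset."""
    if not subset:
        raise ValueError("feature subset must be non-empty")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")

    x = _one_hot(matrix, subset)
    y = np.asarray(matrix.y)
    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)

    metrics: dict[str, list[float]] = {m: [] for m in ("auc", "precision", "recall", "f_score")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_idx, test_idx in splitter.split(x, y):
            y_train, y_test = y[train_idx], y[test_idx]
            if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
                raise ValueError("a fold contains a single outcome class; reduce k_folds")
            model = make_model(model_name, seed, model_params)
            model.fit(x[train_idx], y_train)
            prob = model.predict_proba(x[test_idx])[:, list(model.classes_).index(1)]
            pred = (prob >= 0.5).astype(int)
            precision, recall, f_score, _ = precision_recall_fscore_support(
                y_test, pred, average="binary", pos_label=1, zero_division=0.0
            )
            metrics["auc"].append(float(roc_auc_score(y_test, prob)))
            metrics["precision"].append(float(precision))
            metrics["recall"].append(float(recall))
            metrics["f_score"].append(float(f_score))

    return CvReport(
        model=model_name,
        feature_set=feature_set_name or f"{len(subset)} features",
        k_folds=k_folds,
        seed=seed,
        fold_metrics={k: np.asarray(v) for k, v in metrics.items()},
    )


def compare_feature_sets(
    matrix: FeatureMatrix,
    named_subsets: Mapping[str, Sequence[str]],
    models: Sequence[str] = MODEL_NAMES,
    k_folds: int = 10,
    seed: int = 0,
    model_params: Mapping[str, dict] | None = None,
) -> list[CvReport]:
    """Full cross of feature subsets x models, one CvReport each."""
    if len(named_subsets) < 1:
        raise ValueError("at least one feature subset is required")
    reports = []
    for set_name in named_subsets:
        for model_name in models:
            reports.append(
                run_cv(matrix, list(named_subsets[set_name]), model_name,
                       k_folds=k_folds, seed=seed, model_params=model_params,
                       feature_set_name=set_name)
            )
    return reports
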