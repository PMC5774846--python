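"""Learning layers: barcode-space KNN, tree ensembles, and consensus.

The tree models are scikit-learn ensembles wrapped behind registered
configurations: a regression gradient-boosting setup (20000 trees, depth
8, learning rate 0.005, subsample 0.7, sqrt feature fraction) and the
screening classifiers (GBT with 2000 trees, subsample 0.5, learning rate
0.01 and a 100:1 positive:negative weight ratio; random forest and extra
trees with 2000 trees and balanced-subsample class weights). KNN
regression runs directly on a precomputed barcode-space distance matrix
with k = 3 by default. The screening voter averages the positive-class
probabilities of its member classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)


@dataclass(frozen=True)
class ModelConfig:
    """A named model family with hyperparameters and a seed."""

    family: str  # {"gbt", "rf", "et", "knn"}
    task: str = "regression"  # {"regression", "classification"}
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("gbt", "rf", "et", "knn"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")


#: Positive:negative sample-weight ratio of the screening GBT.
GBT_CLASS_WEIGHT_RATIO = 100.0

REGISTERED_CONFIGS: dict[str, ModelConfig] = {
    "gbt_regression": ModelConfig(
        "gbt",
        "regression",
        dict(
            n_estimators=20000,
            max_depth=8,
            learning_rate=0.005,
            loss="squared_error",
            subsample=0.7,
            max_features="sqrt",
        ),
    ),
    "gbt_screening": ModelConfig(
        "gbt",
        "classification",
        dict(
            n_estimators=2000,
            subsample=0.5,
            learning_rate=0.01,
            max_features="sqrt",
        ),
    ),
    "rf_screening": ModelConfig(
        "rf", "classification", dict(n_estimators=2000, class_weight="balanced_subsample")
    ),
    "et_screening": ModelConfig(
        "et", "classification", dict(n_estimators=2000, class_weight="balanced_subsample")
    ),
    "knn_barcode": ModelConfig("knn", "regression", dict(k=3)),
}


def get_config(name: str, seed: int = 0, **overrides) -> ModelConfig:
    """A registered configuration, optionally with overridden parameters."""
    cfg = REGISTERED_CONFIGS[name]
    params = dict(cfg.params)
    params.update(overrides)
    return replace(cfg, params=params, seed=seed)


def knn_predict(
    distances: np.ndarray,
    train_values: Sequence[float],
    k: int = 3,
    leave_one_out: bool = False,
) -> np.ndarray:
    """Unweighted k-nearest-neighbor regression on a distance matrix.

    ``distances`` is (n_query, n_train); in leave-one-out mode it must be
    the square training matrix and the self-distance is ignored. Ties at
    the k-th distance are broken by stable training order.
    """
    distances = np.asarray(distances, dtype=float)
    y = np.asarray(train_values, dtype=float)
    if k < 1:
        raise ValueError("k must be at least 1")
    n_train = len(y)
    effective = n_train - 1 if leave_one_out else n_train
    if k > effective:
        raise ValueError(f"k={k} exceeds the number of available neighbors {effective}")
    if distances.ndim != 2 or distances.shape[1] != n_train:
        raise ValueError("distance matrix shape does not match training targets")
    preds = np.empty(distances.shape[0])
    for i, row in enumerate(distances):
        order = np.argsort(row, kind="stable")
        if leave_one_out:
            order = order[order != i]
        preds[i] = y[order[:k]].mean()
    return preds


def _backend(cfg: ModelConfig):
    params = dict(cfg.params)
    params.pop("class_weight_ratio", None)
    cls = {
        ("gbt", "regression"): GradientBoostingRegressor,
        ("gbt", "classification"): GradientBoostingClassifier,
        ("rf", "regression"): RandomForestRegressor,
        ("rf", "classification"): RandomForestClassifier,
        ("et", "regression"): ExtraTreesRegressor,
        ("et", "classification"): ExtraTreesClassifier,
    }[(cfg.family, cfg.task)]
    return cls(random_state=cfg.seed, **params)


def fit_predict_trees(
    features: np.ndarray,
    targets: Sequence[float],
    cfg: ModelConfig,
    class_weight_ratio: float | None = None,
):
    """Fit a tree ensemble and return ``(model, training predictions)``.

    Classification predictions are positive-class probabilities. For the
    GBT classifier the positive:negative class weight is applied through
    per-sample weights (ratio defaults to 100:1).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if X.shape[0] != len(y):
        raise ValueError("feature rows and targets misaligned")
    if cfg.family == "knn":
        raise ValueError("use knn_predict for the KNN family")
    model = _backend(cfg)
    sample_weight = None
    if cfg.task == "classification" and cfg.family == "gbt":
        ratio = class_weight_ratio if class_weight_ratio is not None else GBT_CLASS_WEIGHT_RATIO
        sample_weight = np.where(y > 0, ratio, 1.0)
    model.fit(X, y.astype(int) if cfg.task == "classification" else y,
              sample_weight=sample_weight)
    if cfg.task == "classification":
        preds = model.predict_proba(X)[:, 1]
    else:
        preds = model.predict(X)
    return model, preds


def vote_classifiers(models: Sequence, features: np.ndarray) -> np.ndarray:
    """Arithmetic mean of positive-class probabilities over classifiers."""
    if not models:
        raise ValueError("need at least one model")
    X = np.asarray(features, dtype=float)
    n_features = getattr(models[0], "n_features_in_", X.shape[1])
    probs = []
    for model in models:
        if getattr(model, "n_features_in_", n_features) != n_features:
            raise ValueError("models disagree on the feature schema")
        probs.append(model.predict_proba(X)[:, 1])
    return np.mean(probs, axis=0)


def consensus_average(predictions: Sequence[Sequence[float]]) -> np.ndarray:
    """Element-wise mean of aligned prediction vectors."""
    arrays = [np.asarray(p, dtype=float).ravel() for p in predictions]
    if not arrays:
        raise ValueError("need at least one prediction vector")
    length = len(arrays[0])
    if any(len(a) != length for a in arrays):
        raise ValueError("prediction vectors differ in length")
    return np.mean(arrays, axis=0)


def rank_combinations(
    blocks: dict[str, np.ndarray], targets: Sequence[float], seed: int = 0,
    task: str = "regression", n_estimators: int = 200,
) -> list[str]:
    """Order element combinations by ensemble importance on a task.

    Fits one extra-trees model on the concatenation of all blocks and sums
    feature importances per combination; the returned labels are sorted by
    decreasing importance. Persist the result and reuse it at inference.
    """
    labels = list(blocks)
    X = np.concatenate([np.asarray(blocks[l], dtype=float) for l in labels], axis=1)
    y = np.asarray(targets, dtype=float)
    cls = ExtraTreesRegressor if task == "regression" else ExtraTreesClassifier
    model = cls(n_estimators=n_estimators, random_state=seed)
    model.fit(X, y if task == "regression" else y.astype(int))
    scores = {}
    start = 0
    for label in labels:
        width = np.asarray(blocks[label]).shape[1]
        scores[label] = float(model.feature_importances_[start : start + width].sum())
        start += width
    return sorted(labels, key=lambda l: (-scores[l], labels.index(l)))
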