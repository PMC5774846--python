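"""End-to-end screening flow: featurize complexes, train voters, evaluate.

This is the glue used by the command-line interface and the examples: it
computes interactive-distance and electrostatic count features for every
protein-compound complex, trains the three-member voting classifier
(gradient boosting, random forest, extra trees) per leave-one-target-out
round, and reports per-target AUC and enrichment factors.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .learn import fit_predict_trees, get_config, vote_classifiers
from .screen import ScreenResult, leave_one_target_out, training_pool
from .structures import ComplexStructure
from .vectorize import assemble_features, feature_schema

#: Default feature groups of the screening classifier: interactive
#: distance counts over single-element pairs and electrostatic counts.
DEFAULT_SCREEN_GROUPS = ("R-B0-I-BP", "R-B0-CI-C")

#: Ensemble sizes: the registered defaults use 2000 trees; desk-scale runs
#: (tests, examples) pass a smaller value.
VOTER_CONFIGS = ("gbt_screening", "rf_screening", "et_screening")


def featurize_complexes(
    complexes: Sequence[ComplexStructure],
    groups: Sequence[str] = DEFAULT_SCREEN_GROUPS,
) -> pd.DataFrame:
    """Feature matrix (one row per complex) for the named groups."""
    schema = [name for g in groups for name in feature_schema(g)]
    rows = np.empty((len(complexes), len(schema)))
    for i, cx in enumerate(complexes):
        parts = [assemble_features(cx, g).values for g in groups]
        rows[i] = np.concatenate(parts)
    return pd.DataFrame(rows, columns=schema)


def train_voters(
    X: np.ndarray, y: Sequence[int], seed: int, n_estimators: int | None = None
) -> list:
    """Fit the three screening classifiers on one training split."""
    models = []
    for k, name in enumerate(VOTER_CONFIGS):
        overrides = {"n_estimators": n_estimators} if n_estimators else {}
        cfg = get_config(name, seed=seed + k, **overrides)
        model, _ = fit_predict_trees(X, y, cfg)
        models.append(model)
    return models


def run_screening_experiment(
    records: Sequence[tuple[ComplexStructure, str, str]],
    groups: Sequence[str] = DEFAULT_SCREEN_GROUPS,
    seed: int = 0,
    n_estimators: int | None = None,
    exclusions: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, ScreenResult]:
    """Leave-one-target-out screening with the voting classifier.

    Returns the per-target report (AUC, EF2%, EF20%, average row) and the
    pooled scored entries across all test targets.
    """
    complexes = [cx for cx, _, _ in records]
    targets = np.array([t for _, t, _ in records])
    labels = np.array([1 if lab == "active" else 0 for _, _, lab in records])
    X = featurize_complexes(complexes, groups).to_numpy()
    unique_targets = list(dict.fromkeys(targets))
    if len(unique_targets) < 2:
        raise ValueError("leave-one-target-out needs at least two targets")
    results: dict[str, ScreenResult] = {}
    pooled_scores: list[float] = []
    pooled_labels: list[str] = []
    for test_target in unique_targets:
        pool = set(training_pool(unique_targets, test_target, exclusions))
        train_mask = np.isin(targets, list(pool))
        test_mask = targets == test_target
        models = train_voters(X[train_mask], labels[train_mask], seed, n_estimators)
        probs = vote_classifiers(models, X[test_mask])
        labs = ["active" if l else "decoy" for l in labels[test_mask]]
        results[test_target] = ScreenResult.from_arrays(probs, labs, test_target)
        pooled_scores.extend(probs.tolist())
        pooled_labels.extend(labs)
    report = leave_one_target_out(results, exclusions)
    pooled = ScreenResult.from_arrays(pooled_scores, pooled_labels, "pooled")
    return report, pooled
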