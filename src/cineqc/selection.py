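"""Univariate feature selection: correlation pruning plus task-specific ranking.

The pipeline mirrors common radiomics practice: first remove redundant
features (pairwise Pearson |rho| > 0.8 against an already-kept feature, greedy
in canonical extraction order), then rank the survivors by mutual
information with the continuous Dice target (regression) or by the one-way
ANOVA F statistic against the good/bad label (classification), keeping at
most 12 features.

Note the pruning uses |rho|, not signed rho: an anti-correlated feature
carries the same information as a correlated one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif, mutual_info_regression
from sklearn.model_selection import KFold, StratifiedKFold

MAX_FEATURES = 12

__all__ = [
    "MAX_FEATURES",
    "SelectionResult",
    "correlation_filter",
    "rank_mutual_information",
    "rank_anova_f",
    "select_features",
    "sweep_k",
]


@dataclass
class SelectionResult:
    """Outcome of a selection step: kept names (ranked), scores, provenance."""

    kept: list[str]
    scores: dict[str, float]
    task: str  # "regression" | "classification" | "correlation"
    k: int | None = None
    removed_by_correlation: list[str] = field(default_factory=list)
    threshold: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k is not None and self.k > MAX_FEATURES:
            raise ValueError(f"k={self.k} exceeds the cap of {MAX_FEATURES} features")
        overlap = set(self.kept) & set(self.removed_by_correlation)
        if overlap:
            raise ValueError(f"features both kept and removed: {sorted(overlap)}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            return cls(**json.load(fh))


def correlation_filter(table: pd.DataFrame, threshold: float = 0.8) -> SelectionResult:
    """Greedy redundancy pruning in canonical (column) order.

    Scanning columns left to right, a feature is dropped iff its |Pearson
    rho| with some already-kept feature exceeds ``threshold``.  Constant
    (zero-variance) columns are dropped with reason recorded; the result is
    deterministic and invariant to row order.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    X = table.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values; exclude failed extractions first")
    cols = list(table.columns)
    sd = X.std(axis=0)
    kept_idx: list[int] = []
    removed: list[str] = []
    scores: dict[str, float] = {}
    for j, name in enumerate(cols):
        if sd[j] == 0:
            removed.append(name)
            scores[name] = np.nan  # zero variance: correlation undefined
            continue
        worst = 0.0
        drop = False
        for i in kept_idx:
            r = abs(float(np.corrcoef(X[:, i], X[:, j])[0, 1]))
            worst = max(worst, r)
            if r > threshold:
                drop = True
                break
        scores[name] = worst
        if drop:
            removed.append(name)
        else:
            kept_idx.append(j)
    return SelectionResult(kept=[cols[i] for i in kept_idx], scores=scores,
                           task="correlation", removed_by_correlation=removed,
                           threshold=threshold)


def _check_k(k: int) -> None:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > MAX_FEATURES:
        raise ValueError(f"k={k} exceeds the cap of {MAX_FEATURES} features")


def rank_mutual_information(table: pd.DataFrame, target_dsc, k: int,
                            seed: int = 0) -> SelectionResult:
    """Top-k features by estimated mutual information with the Dice target.

    Uses the k-nearest-neighbour MI estimator for continuous targets
    (3 neighbours), seeded for reproducibility.
    """
    _check_k(k)
    y = np.asarray(target_dsc, dtype=np.float64)
    mi = mutual_info_regression(table.to_numpy(np.float64), y,
                                n_neighbors=3, random_state=seed)
    order = np.argsort(-mi, kind="stable")
    kept = [table.columns[i] for i in order[: min(k, table.shape[1])]]
    return SelectionResult(kept=kept, scores=dict(zip(table.columns, map(float, mi))),
                           task="regression", k=k, seed=seed)


def rank_anova_f(table: pd.DataFrame, labels, k: int) -> SelectionResult:
    """Top-k features by one-way ANOVA F statistic between good/bad groups."""
    _check_k(k)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both quality classes must be present for ANOVA ranking")
    F, _ = f_classif(table.to_numpy(np.float64), y)
    F = np.nan_to_num(F, nan=0.0)
    order = np.argsort(-F, kind="stable")
    kept = [table.columns[i] for i in order[: min(k, table.shape[1])]]
    return SelectionResult(kept=kept, scores=dict(zip(table.columns, map(float, F))),
                           task="classification", k=k)


def select_features(table: pd.DataFrame, target, task: str, k: int = MAX_FEATURES,
                    rho_threshold: float = 0.8, seed: int = 0) -> SelectionResult:
    """Full selection pipeline: |rho| pruning then task-specific top-k ranking."""
    pruned = correlation_filter(table, threshold=rho_threshold)
    survivors = table[pruned.kept]
    if task == "regression":
        ranked = rank_mutual_information(survivors, target, k=k, seed=seed)
    elif task == "classification":
        ranked = rank_anova_f(survivors, target, k=k)
    else:
        raise ValueError(f"task must be 'regression' or 'classification', got {task!r}")
    ranked.removed_by_correlation = pruned.removed_by_correlation
    ranked.threshold = rho_threshold
    return ranked


def sweep_k(table: pd.DataFrame, target, task: str, k_max: int = MAX_FEATURES,
            cv_folds: int = 5, seed: int = 0, estimator=None) -> int:
    """Pick the feature count by cross-validated task score.

    For each k in 1..k_max the top-k features feed a cross-validated model
    (MAE for regression, accuracy for classification by default); the best
    mean score wins, ties broken towards the smaller k.
    """
    from sklearn.base import clone
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestClassifier
    from sklearn.model_selection import cross_val_score

    y = np.asarray(target)
    k_max = min(k_max, MAX_FEATURES, table.shape[1])
    if estimator is None:
        estimator = (GradientBoostingRegressor(random_state=seed) if task == "regression"
                     else RandomForestClassifier(random_state=seed, n_estimators=200))
    scoring = "neg_mean_absolute_error" if task == "regression" else "accuracy"
    cv = (KFold(cv_folds, shuffle=True, random_state=seed) if task == "regression"
          else StratifiedKFold(cv_folds, shuffle=True, random_state=seed))
    best_k, best_score = 1, -np.inf
    for k in range(1, k_max + 1):
        sel = select_features(table, y, task, k=k, seed=seed)
        score = float(np.mean(cross_val_score(clone(estimator), table[sel.kept].to_numpy(np.float64),
                                              y, cv=cv, scoring=scoring)))
        if score > best_score + 1e-12:  # strict improvement: ties keep smaller k
            best_k, best_score = k, score
    return best_k
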