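"""Dice regression, good/bad classification, and the two-stage QC filter.

Defaults follow what works best for this task: gradient-boosted regression
trees (GBR) for continuous Dice prediction and a random forest (RFC) for
good/bad classification, both tuned by 5-fold cross-validated grid search.
Classifier model selection optimises the negative detection rate
NDR = TN/(TN+FN) — the fraction of actually-bad segmentations caught —
with AUC as tie-break, because a QC system's first duty is not to let bad
segmentations through.  Class imbalance is handled with inverse-frequency
weights (``balance_weights``) applied as sample weights.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import mean_absolute_error, r2_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.model_selection import ParameterGrid

from .core_metrics import ConfusionCounts, ndr, quality_cutoff
from .selection import SelectionResult

__all__ = [
    "QCModelBundle",
    "QualityRecord",
    "DEFAULT_GBR_GRID",
    "DEFAULT_RFC_GRID",
    "balance_weights",
    "train_regressor",
    "train_classifier",
    "predict_dsc",
    "predict_quality",
    "records_from_predictions",
    "evaluate",
    "two_stage_filter",
]

DEFAULT_GBR_GRID = {"n_estimators": [100, 300], "max_depth": [2, 3, 4],
                    "learning_rate": [0.05, 0.1]}
DEFAULT_RFC_GRID = {"n_estimators": [200, 500], "max_depth": [None, 8]}

#: alternative estimators exposed behind the same interface (untuned defaults)
REGRESSORS = {"gbr": GradientBoostingRegressor, "rfr": RandomForestRegressor}
CLASSIFIERS = {"rfc": RandomForestClassifier, "gbc": GradientBoostingClassifier}


@dataclass
class QCModelBundle:
    """A fitted QC model with everything needed to reapply it."""

    structure: str
    level: str  # "2D" | "3D"
    task: str  # "regression" | "classification"
    selection: SelectionResult
    estimator: object
    weight_scheme: str
    seed: int
    grid: dict
    best_params: dict
    train_fingerprint: str

    @property
    def feature_names(self) -> list[str]:
        return list(self.selection.kept)

    def save(self, path) -> None:
        """Pickle the bundle and write a human-readable JSON sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        meta = {
            "structure": self.structure, "level": self.level, "task": self.task,
            "selected_features": self.feature_names,
            "weight_scheme": self.weight_scheme, "seed": self.seed,
            "grid": {k: [str(v) for v in vs] for k, vs in self.grid.items()},
            "best_params": {k: str(v) for k, v in self.best_params.items()},
            "train_fingerprint": self.train_fingerprint,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @staticmethod
    def load(path) -> "QCModelBundle":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class QualityRecord:
    """Unit of evaluation: one segmentation's actual and predicted quality."""

    subject: int
    structure: str
    level: str
    slice_index: int
    variant: int
    actual_dsc: float
    predicted_dsc: float
    actual_label: str  # "good" | "bad"
    predicted_label: str
    predicted_proba: float = np.nan  # P(predicted good)
    preset: str = ""


def balance_weights(labels) -> np.ndarray:
    """Inverse-frequency sample weights: w = n_total / (n_classes * n_class).

    The weighted mass of each class is equal and the weights sum to
    n_total.  A single-class input gets uniform weights.
    """
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("need at least one sample")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        return np.ones(y.size)
    w = {c: y.size / (len(classes) * n) for c, n in zip(classes, counts)}
    return np.array([w[v] for v in y])


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def _matrix(table: pd.DataFrame, selection: SelectionResult) -> np.ndarray:
    missing = [f for f in selection.kept if f not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing selected features: {missing}")
    return table[selection.kept].to_numpy(np.float64)


def train_regressor(table: pd.DataFrame, target_dsc, selection: SelectionResult,
                    grid: dict | None = None, seed: int = 0, structure: str = "",
                    level: str = "2D", kind: str = "gbr") -> QCModelBundle:
    """Fit a Dice regressor with 5-fold CV grid search (MAE criterion).

    Sample weights balance the good/bad groups (cutoff by ``level``) so the
    scarcer quality class is not drowned out; the winning configuration is
    refit on all rows.  Deterministic given ``seed``.
    """
    y = np.asarray(target_dsc, dtype=np.float64)
    if len(table) == 0:
        raise ValueError("empty training table")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("target Dice values must lie in [0, 1]")
    X = _matrix(table, selection)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in training table")
    grid = DEFAULT_GBR_GRID if grid is None else grid
    labels = np.where(y < quality_cutoff("slice2D" if level == "2D" else "subject3D"),
                      "bad", "good")
    w = balance_weights(labels)
    base = REGRESSORS[kind](random_state=seed)
    cv = KFold(5, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, cv=cv, scoring="neg_mean_absolute_error",
                          refit=True, n_jobs=1)
    search.fit(X, y, sample_weight=w)
    return QCModelBundle(structure=structure, level=level, task="regression",
                         selection=selection, estimator=search.best_estimator_,
                         weight_scheme="balanced_by_quality_group", seed=seed,
                         grid=grid, best_params=search.best_params_,
                         train_fingerprint=_fingerprint(X, y))


def train_classifier(table: pd.DataFrame, labels, selection: SelectionResult,
                     grid: dict | None = None, seed: int = 0, structure: str = "",
                     level: str = "2D", kind: str = "rfc") -> QCModelBundle:
    """Fit a good/bad classifier; grid search maximises CV NDR, tie-break AUC.

    NDR is computed fold-wise as the fraction of actually-bad samples
    predicted bad.  Class weights are balanced; the winner is refit on all
    rows.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both quality classes must be present to train a classifier")
    X = _matrix(table, selection)
    grid = DEFAULT_RFC_GRID if grid is None else grid
    cv = StratifiedKFold(5, shuffle=True, random_state=seed)
    best = None  # (ndr, auc, params)
    for params in ParameterGrid(grid):
        ndrs, aucs = [], []
        for tr, te in cv.split(X, y):
            est = CLASSIFIERS[kind](random_state=seed, class_weight="balanced", **params) \
                if kind == "rfc" else CLASSIFIERS[kind](random_state=seed, **params)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[te])
            bad = y[te] == "bad"
            if bad.any():
                ndrs.append(float((pred[bad] == "bad").mean()))
            proba = est.predict_proba(X[te])[:, list(est.classes_).index("good")]
            if len(np.unique(y[te])) == 2:
                aucs.append(float(roc_auc_score(y[te] == "good", proba)))
        score = (float(np.mean(ndrs)) if ndrs else 0.0,
                 float(np.mean(aucs)) if aucs else 0.0)
        if best is None or score > best[0]:
            best = (score, dict(params))
    final = CLASSIFIERS[kind](random_state=seed, class_weight="balanced", **best[1]) \
        if kind == "rfc" else CLASSIFIERS[kind](random_state=seed, **best[1])
    final.fit(X, y)
    return QCModelBundle(structure=structure, level=level, task="classification",
                         selection=selection, estimator=final,
                         weight_scheme="class_weight=balanced", seed=seed,
                         grid=grid, best_params=best[1],
                         train_fingerprint=hashlib.sha256(
                             np.ascontiguousarray(X).tobytes()
                             + "|".join(map(str, y)).encode()).hexdigest()[:16])


def predict_dsc(bundle: QCModelBundle, table: pd.DataFrame) -> np.ndarray:
    """Predicted Dice for each row, clipped to [0, 1].

    Raises when a selected feature is missing from the table; rows are
    assumed to be successful extractions (exclude failed records upstream).
    """
    if bundle.task != "regression":
        raise ValueError("bundle is not a regression model")
    X = _matrix(table, bundle.selection)
    raw = np.asarray(bundle.estimator.predict(X), dtype=np.float64)
    return np.clip(raw, 0.0, 1.0)


def predict_quality(bundle: QCModelBundle, table: pd.DataFrame,
                    threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """(labels, P(good)) from a classification bundle; threshold on P(good)."""
    if bundle.task != "classification":
        raise ValueError("bundle is not a classification model")
    X = _matrix(table, bundle.selection)
    proba = bundle.estimator.predict_proba(X)[:, list(bundle.estimator.classes_).index("good")]
    labels = np.where(proba >= threshold, "good", "bad")
    return labels, proba


def records_from_predictions(index: pd.DataFrame, predicted_dsc, predicted_label,
                             predicted_proba=None, level: str = "2D") -> list[QualityRecord]:
    """Zip a dataset index with model outputs into QualityRecord units."""
    cut = quality_cutoff("slice2D" if level == "2D" else "subject3D")
    proba = np.full(len(index), np.nan) if predicted_proba is None else np.asarray(predicted_proba)
    recs = []
    for i, (_, row) in enumerate(index.iterrows()):
        recs.append(QualityRecord(
            subject=int(row["subject"]), structure=str(row["structure"]),
            level=level, slice_index=int(row.get("slice_index", -1)),
            variant=int(row["variant"]), actual_dsc=float(row["actual_dsc"]),
            predicted_dsc=float(predicted_dsc[i]),
            actual_label="bad" if row["actual_dsc"] < cut else "good",
            predicted_label=str(predicted_label[i]), predicted_proba=float(proba[i]),
            preset=str(row.get("preset", ""))))
    return recs


def evaluate(records: list[QualityRecord]) -> dict:
    """Regression and classification metrics over a record set.

    Returns MAE, R2, AUC (when probabilities and both classes exist),
    confusion counts, NDR (None with a warning field when no actual-bad
    records), and per-disease MAE when presets are present.
    """
    if not records:
        raise ValueError("no records to evaluate")
    actual = np.array([r.actual_dsc for r in records])
    pred = np.array([r.predicted_dsc for r in records])
    a_lab = np.array([r.actual_label for r in records])
    p_lab = np.array([r.predicted_label for r in records])
    report: dict = {
        "n": len(records),
        "mae": float(mean_absolute_error(actual, pred)),
        "r2": float(r2_score(actual, pred)) if len(records) > 1 else np.nan,
    }
    counts = ConfusionCounts(
        tp=int(((a_lab == "good") & (p_lab == "good")).sum()),
        fp=int(((a_lab == "good") & (p_lab == "bad")).sum()),
        tn=int(((a_lab == "bad") & (p_lab == "bad")).sum()),
        fn=int(((a_lab == "bad") & (p_lab == "good")).sum()),
    )
    report["confusion"] = counts
    if counts.tn + counts.fn > 0:
        report["ndr"] = ndr(counts)
    else:
        report["ndr"] = None
        report["warning"] = "NDR omitted: no actual-bad records"
    proba = np.array([r.predicted_proba for r in records])
    if np.all(np.isfinite(proba)) and len(np.unique(a_lab)) == 2:
        report["auc"] = float(roc_auc_score(a_lab == "good", proba))
    else:
        report["auc"] = None
    presets = {r.preset for r in records if r.preset}
    if presets:
        report["mae_by_disease"] = {
            p: float(np.mean(np.abs(actual[[r.preset == p for r in records]]
                                    - pred[[r.preset == p for r in records]])))
            for p in sorted(presets)}
    return report


def two_stage_filter(records: list[QualityRecord]) -> dict:
    """Trust Dice estimates only for predicted-good segmentations.

    Returns the kept (predicted-good) records, the MAE over everything,
    the MAE over the kept subset, and the improvement mae_all - mae_kept
    (positive when the classifier removed the worst predictions).
    """
    if not records:
        raise ValueError("no records")
    errors = np.array([abs(r.actual_dsc - r.predicted_dsc) for r in records])
    keep = np.array([r.predicted_label == "good" for r in records])
    mae_all = float(errors.mean())
    out = {"kept": [r for r, k in zip(records, keep) if k],
           "removed": [r for r, k in zip(records, keep) if not k],
           "mae_all": mae_all}
    if keep.any():
        out["mae_kept"] = float(errors[keep].mean())
        out["improvement"] = mae_all - out["mae_kept"]
    else:
        out["mae_kept"] = None
        out["improvement"] = None
        out["warning"] = "all records predicted bad; improvement undefined"
    return out
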