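"""End-to-end QC experiment glue: phantoms -> perturbed masks -> features -> models.

The feature table is built in a streaming fashion (one perturbed candidate
at a time) so large cohorts never hold all segmentations in memory.  Rows
are (subject, structure, variant, level, slice) with the 102/107 feature
columns plus the actual Dice of that candidate against ground truth —
exactly what the regressor and classifier train on.

Train/test splits are grouped by subject: slices and variants of one
subject never straddle the split, so held-out metrics measure generalisation
to unseen hearts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_metrics import dsc, quality_cutoff
from .phantom import PerturbationSpec, calibrate_severity, generate_cohort, perturb_mask, variant_targets
from .qc_models import (
    QCModelBundle,
    evaluate,
    predict_dsc,
    predict_quality,
    records_from_predictions,
    train_classifier,
    train_regressor,
    two_stage_filter,
)
from .radiomics import FeatureSettings, extract_2d, extract_3d
from .selection import select_features

__all__ = ["build_feature_table", "split_by_subject", "run_qc_experiment"]

META_COLS = ("subject", "structure", "variant", "level", "slice_index",
             "actual_dsc", "preset", "mode", "empty_pair", "failed")

DEFAULT_DSC_GRID = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def build_feature_table(cohort, n_variants: int = 32,
                        dsc_grid=DEFAULT_DSC_GRID, seed: int = 0,
                        structures=("RVC", "MYO", "LVC"), level: str = "2D",
                        settings: FeatureSettings = FeatureSettings(),
                        slice_stride: int = 1) -> pd.DataFrame:
    """Radiomics QC table over a phantom cohort and its degraded variants.

    Per subject x structure x variant one candidate segmentation is produced
    (severity calibrated to a Dice target cycled from ``dsc_grid``); features
    are extracted from the image restricted to the *candidate* mask, and the
    candidate's true Dice is stored as the training target.  2D rows skip
    slices where both truth and candidate are empty (``empty_pair``) and
    flag failed extractions instead of raising.
    """
    rng = np.random.default_rng(seed)
    cal_modes = ("dilate", "erode", "boundary_jitter", "translate")
    targets = variant_targets(n_variants, dsc_grid)
    rows = []
    for si, (params, img, gt_labels) in enumerate(cohort):
        for structure in structures:
            gt = gt_labels.structure_mask(structure)
            for v in range(n_variants):
                target = targets[v]
                mode = cal_modes[int(rng.integers(len(cal_modes)))]
                pseed = int(rng.integers(0, 2**31 - 1))
                try:
                    spec = calibrate_severity(gt_labels, structure, target, mode, seed=pseed)
                except ValueError:
                    spec = PerturbationSpec(mode=mode, severity=1.0, seed=pseed)
                pert = perturb_mask(gt_labels, spec, structure).structure_mask(structure)
                base = {"subject": si, "structure": structure, "variant": v,
                        "preset": params.preset, "mode": spec.mode}
                if level == "2D":
                    for k in range(0, gt.shape[0], slice_stride):
                        if not (gt[k].any() or pert[k].any()):
                            continue  # structure genuinely absent: no QC record
                        fv = extract_2d(img.grid[k], pert[k], settings,
                                        spacing=img.spacing[1:], structure=structure)
                        row = dict(base, level="2D", slice_index=k,
                                   actual_dsc=dsc(pert[k], gt[k]),
                                   empty_pair=False, failed=fv.failed)
                        row.update(fv.values)
                        rows.append(row)
                else:
                    fv = extract_3d(img, pert, settings, structure=structure)
                    row = dict(base, level="3D", slice_index=-1,
                               actual_dsc=dsc(pert, gt), empty_pair=False,
                               failed=fv.failed)
                    row.update(fv.values)
                    rows.append(row)
    return pd.DataFrame(rows)


def split_by_subject(table: pd.DataFrame, test_fraction: float = 0.3,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grouped train/test split: whole subjects go to one side or the other."""
    subjects = np.array(sorted(table["subject"].unique()))
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n_test = max(1, int(round(test_fraction * len(subjects))))
    test_ids = set(subjects[:n_test].tolist())
    mask = table["subject"].isin(test_ids)
    return table[~mask].copy(), table[mask].copy()


def run_qc_experiment(table: pd.DataFrame, structure: str, level: str = "2D",
                      seed: int = 0, test_fraction: float = 0.3,
                      k: int = 12) -> dict:
    """Select features, train GBR + RFC on training subjects, evaluate held out.

    Returns a report with held-out regression metrics (MAE, R2, rank
    correlation), classification metrics (NDR, AUC), the two-stage filter
    outcome, and the fitted bundles.
    """
    from scipy.stats import spearmanr

    sub = table[(table["structure"] == structure) & (table["level"] == level)
                & (~table["failed"]) ].copy()
    if sub.empty:
        raise ValueError(f"no usable rows for {structure} at level {level}")
    feats = feature_columns(sub)
    train, test = split_by_subject(sub, test_fraction=test_fraction, seed=seed)

    cut = quality_cutoff("slice2D" if level == "2D" else "subject3D")
    y_train = train["actual_dsc"].to_numpy(np.float64)
    y_test = test["actual_dsc"].to_numpy(np.float64)
    lab_train = np.where(y_train < cut, "bad", "good")

    sel_reg = select_features(train[feats], y_train, "regression", k=k, seed=seed)
    reg = train_regressor(train[feats], y_train, sel_reg, seed=seed,
                          structure=structure, level=level)
    pred = predict_dsc(reg, test[feats])

    sel_clf = select_features(train[feats], lab_train, "classification", k=k, seed=seed)
    clf = train_classifier(train[feats], lab_train, sel_clf, seed=seed,
                           structure=structure, level=level)
    plab, proba = predict_quality(clf, test[feats])

    records = records_from_predictions(test, pred, plab, proba, level=level)
    report = evaluate(records)
    rho = spearmanr(y_test, pred).statistic if len(test) > 2 else np.nan
    report["rank_correlation"] = float(rho)
    report["two_stage"] = two_stage_filter(records)
    report["n_train"] = len(train)
    report["n_test"] = len(test)
    report["regressor"] = reg
    report["classifier"] = clf
    report["records"] = records
    return report
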