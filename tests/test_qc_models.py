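"""Balanced weights, regressor/classifier training, evaluation, two-stage filter."""

import numpy as np
import pandas as pd
import pytest

from cineqc.qc_models import (
    QualityRecord,
    balance_weights,
    evaluate,
    predict_dsc,
    predict_quality,
    train_classifier,
    train_regressor,
    two_stage_filter,
)
from cineqc.selection import SelectionResult

SMALL_GBR_GRID = {"n_estimators": [50], "max_depth": [2, 3], "learning_rate": [0.1]}
SMALL_RFC_GRID = {"n_estimators": [100], "max_depth": [None, 4]}


def _selection(names, task="regression"):
    return SelectionResult(kept=list(names), scores={n: 1.0 for n in names}, task=task)


@pytest.fixture(scope="module")
def toy_table():
    """DSC is a clean monotone function of one feature, plus distractors."""
    rng = np.random.default_rng(7)
    n = 400
    y = rng.uniform(0, 1, n)
    return pd.DataFrame({"signal": y, "noise1": rng.random(n),
                         "noise2": rng.random(n)}), y


class TestBalanceWeights:
    def test_balanced_classes_unit_weights(self):
        w = balance_weights(["good"] * 10 + ["bad"] * 10)
        np.testing.assert_allclose(w, 1.0)

    def test_inverse_frequency(self):
        w = balance_weights(["good"] * 90 + ["bad"] * 10)
        np.testing.assert_allclose(w[:90], 5 / 9)
        np.testing.assert_allclose(w[90:], 5.0)

    def test_weights_sum_to_n(self, rng):
        labels = rng.choice(["good", "bad"], size=73, p=[0.8, 0.2])
        assert balance_weights(labels).sum() == pytest.approx(73.0)

    def test_single_class_uniform(self):
        np.testing.assert_allclose(balance_weights(["good"] * 5), 1.0)


class TestRegressor:
    def test_learns_identity_feature(self, toy_table):
        tab, y = toy_table
        bundle = train_regressor(tab, y, _selection(["signal"]),
                                 grid=SMALL_GBR_GRID, seed=0)
        pred = predict_dsc(bundle, tab)
        assert np.mean(np.abs(pred - y)) < 0.01

    def test_deterministic_given_seed(self, toy_table):
        tab, y = toy_table
        kw = dict(grid=SMALL_GBR_GRID, seed=3)
        p1 = predict_dsc(train_regressor(tab, y, _selection(["signal", "noise1"]), **kw), tab)
        p2 = predict_dsc(train_regressor(tab, y, _selection(["signal", "noise1"]), **kw), tab)
        np.testing.assert_array_equal(p1, p2)

    def test_predictions_clipped_to_unit_interval(self, toy_table):
        tab, y = toy_table
        bundle = train_regressor(tab, y, _selection(["signal"]), grid=SMALL_GBR_GRID, seed=0)
        wild = pd.DataFrame({"signal": [-5.0, 5.0], "noise1": [0, 0], "noise2": [0, 0]})
        pred = predict_dsc(bundle, wild)
        assert pred.min() >= 0.0 and pred.max() <= 1.0

    def test_missing_selected_feature_named_in_error(self, toy_table):
        tab, y = toy_table
        bundle = train_regressor(tab, y, _selection(["signal"]), grid=SMALL_GBR_GRID, seed=0)
        with pytest.raises(ValueError, match="signal"):
            predict_dsc(bundle, tab.drop(columns=["signal"]).rename(columns={"noise1": "x"}))

    def test_batch_equals_single(self, toy_table):
        tab, y = toy_table
        bundle = train_regressor(tab, y, _selection(["signal"]), grid=SMALL_GBR_GRID, seed=0)
        batch = predict_dsc(bundle, tab.head(5))
        singles = [predict_dsc(bundle, tab.iloc[[i]])[0] for i in range(5)]
        np.testing.assert_allclose(batch, singles)

    def test_rejects_out_of_range_target(self, toy_table):
        tab, _ = toy_table
        with pytest.raises(ValueError):
            train_regressor(tab, np.full(len(tab), 1.5), _selection(["signal"]),
                            grid=SMALL_GBR_GRID)


class TestClassifier:
    def test_separable_data_perfect_ndr(self, toy_table):
        tab, y = toy_table
        labels = np.where(y < 0.7, "bad", "good")
        bundle = train_classifier(tab, labels, _selection(["signal"], "classification"),
                                  grid=SMALL_RFC_GRID, seed=0)
        pred, proba = predict_quality(bundle, tab)
        bad = labels == "bad"
        assert (pred[bad] == "bad").mean() == 1.0
        assert proba.shape == (len(tab),)

    def test_single_class_rejected(self, toy_table):
        tab, _ = toy_table
        with pytest.raises(ValueError, match="both"):
            train_classifier(tab, ["good"] * len(tab),
                             _selection(["signal"], "classification"))

    def test_deterministic_given_seed(self, toy_table):
        tab, y = toy_table
        labels = np.where(y < 0.7, "bad", "good")
        kw = dict(grid=SMALL_RFC_GRID, seed=5)
        sel = _selection(["signal", "noise1"], "classification")
        v1, _ = predict_quality(train_classifier(tab, labels, sel, **kw), tab)
        v2, _ = predict_quality(train_classifier(tab, labels, sel, **kw), tab)
        assert (v1 == v2).all()


def _records(actual, predicted, predicted_label=None, proba=None):
    recs = []
    for i, (a, p) in enumerate(zip(actual, predicted)):
        plab = predicted_label[i] if predicted_label else ("bad" if p < 0.7 else "good")
        recs.append(QualityRecord(
            subject=0, structure="LVC", level="2D", slice_index=i, variant=0,
            actual_dsc=a, predicted_dsc=p,
            actual_label="bad" if a < 0.7 else "good", predicted_label=plab,
            predicted_proba=proba[i] if proba else np.nan))
    return recs


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate(_records([0.5, 0.8, 0.9], [0.5, 0.8, 0.9]))
        assert rep["mae"] == 0.0
        assert rep["r2"] == pytest.approx(1.0)
        assert rep["ndr"] == 1.0

    def test_constant_prediction_zero_r2(self):
        actual = [0.8, 0.9, 1.0, 0.7]
        mean = float(np.mean(actual))
        rep = evaluate(_records(actual, [mean] * 4))
        assert rep["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_mae_arithmetic(self):
        """Errors 0.1, 0.2, 0.3, 0.4 -> MAE 0.25 (hand computed)."""
        rep = evaluate(_records([0.9, 0.9, 0.9, 0.9], [0.8, 0.7, 0.6, 0.5],
                                predicted_label=["good"] * 4))
        assert rep["mae"] == pytest.approx(0.25)

    def test_ndr_omitted_without_actual_bad(self):
        rep = evaluate(_records([0.9, 0.95], [0.9, 0.95]))
        assert rep["ndr"] is None
        assert "warning" in rep

    def test_confusion_layout(self):
        rep = evaluate(_records([0.9, 0.5, 0.5, 0.9], [0.9, 0.5, 0.9, 0.5]))
        c = rep["confusion"]
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)
        assert rep["ndr"] == 0.5


class TestTwoStageFilter:
    def test_all_good_no_change(self):
        recs = _records([0.9, 0.8], [0.85, 0.75], predicted_label=["good", "good"])
        out = two_stage_filter(recs)
        assert out["improvement"] == pytest.approx(0.0)

    def test_removing_worst_errors_improves_mae(self):
        # classifier flags exactly the two worst predictions
        recs = _records([0.9, 0.9, 0.2, 0.1], [0.85, 0.88, 0.8, 0.9],
                        predicted_label=["good", "good", "bad", "bad"])
        out = two_stage_filter(recs)
        assert out["improvement"] > 0
        assert len(out["kept"]) == 2

    def test_partition(self):
        recs = _records([0.9, 0.5, 0.7], [0.8, 0.6, 0.7])
        out = two_stage_filter(recs)
        assert len(out["kept"]) + len(out["removed"]) == 3

    def test_all_bad_flagged_undefined(self):
        recs = _records([0.9, 0.9], [0.5, 0.4], predicted_label=["bad", "bad"])
        out = two_stage_filter(recs)
        assert out["improvement"] is None and "warning" in out
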