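"""Overlap metrics against brute-force pixel counting, labels and stacking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cineqc.core_metrics import (
    ConfusionCounts,
    QualityLevel,
    dsc,
    empty_pair,
    iou,
    label_quality,
    ndr,
    precision_recall,
    stack_slices,
)


def _brute_force(pred, ref):
    """Independent oracle: explicit per-pixel counting with python loops."""
    tp = fp = fn = 0
    for p, r in zip(np.asarray(pred).ravel(), np.asarray(ref).ravel()):
        if p and r:
            tp += 1
        elif p:
            fp += 1
        elif r:
            fn += 1
    n_pred, n_ref = tp + fp, tp + fn
    d = 2 * tp / (n_pred + n_ref) if (n_pred + n_ref) else 1.0
    union = tp + fp + fn
    j = tp / union if union else 1.0
    prec = tp / n_pred if n_pred else 1.0
    rec = tp / n_ref if n_ref else 1.0
    return d, j, prec, rec


class TestDice:
    def test_identity(self):
        m = np.zeros((10, 10), bool)
        m[2:7, 2:7] = True  # 25 true pixels
        assert dsc(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = True
        b[4, 4] = True
        assert dsc(a, b) == 0.0

    def test_partial_overlap(self):
        # |pred|=4, |ref|=6, intersection=3 -> 2*3/10 = 0.6
        pred = np.zeros((4, 4), bool)
        ref = np.zeros((4, 4), bool)
        pred.ravel()[[0, 1, 2, 3]] = True
        ref.ravel()[[1, 2, 3, 8, 9, 10]] = True
        assert dsc(pred, ref) == pytest.approx(0.6)

    def test_both_empty_is_perfect(self):
        e = np.zeros((3, 3), bool)
        assert dsc(e, e) == 1.0
        assert iou(e, e) == 1.0
        assert empty_pair(e, e)

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(3, 3\).*\(4, 4\)"):
            dsc(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestIoU:
    def test_counts(self):
        # intersection 3, union 7
        pred = np.zeros((3, 3), bool)
        ref = np.zeros((3, 3), bool)
        pred.ravel()[[0, 1, 2, 3, 4]] = True
        ref.ravel()[[2, 3, 4, 5, 6]] = True
        assert iou(pred, ref) == pytest.approx(3 / 7)

    def test_algebraic_identity_with_dsc(self, rng):
        for _ in range(50):
            a = rng.random((6, 6)) < 0.4
            b = rng.random((6, 6)) < 0.4
            j = iou(a, b)
            assert dsc(a, b) == pytest.approx(2 * j / (1 + j), abs=1e-12)


class TestPrecisionRecall:
    def test_strict_subset(self):
        ref = np.zeros((5, 5), bool)
        ref[1:4, 1:4] = True
        pred = np.zeros((5, 5), bool)
        pred[2, 2] = True
        p, r = precision_recall(pred, ref)
        assert p == 1.0 and r < 1.0

    def test_counts(self):
        # tp=3, fp=1, fn=2
        pred = np.zeros((3, 3), bool)
        ref = np.zeros((3, 3), bool)
        pred.ravel()[[0, 1, 2, 3]] = True
        ref.ravel()[[0, 1, 2, 4, 5]] = True
        assert precision_recall(pred, ref) == (pytest.approx(0.75), pytest.approx(0.6))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 511), st.integers(0, 511))
def test_metrics_match_pixel_count_oracle(i, j):
    pred = np.array([(i >> k) & 1 for k in range(9)], bool).reshape(3, 3)
    ref = np.array([(j >> k) & 1 for k in range(9)], bool).reshape(3, 3)
    d, u, p, r = _brute_force(pred, ref)
    assert dsc(pred, ref) == pytest.approx(d, abs=1e-12)
    assert iou(pred, ref) == pytest.approx(u, abs=1e-12)
    got_p, got_r = precision_recall(pred, ref)
    assert (got_p, got_r) == (pytest.approx(p), pytest.approx(r))
    # symmetry and ordering
    assert dsc(ref, pred) == pytest.approx(dsc(pred, ref))
    assert dsc(pred, ref) >= iou(pred, ref)


class TestNdr:
    def test_basic(self):
        assert ndr(ConfusionCounts(0, 0, tn=9, fn=1)) == pytest.approx(0.9)

    def test_all_caught(self):
        assert ndr(ConfusionCounts(5, 2, tn=4, fn=0)) == 1.0

    def test_undefined_without_actual_bad(self):
        with pytest.raises(ValueError, match="no actual-bad"):
            ndr(ConfusionCounts(5, 1, tn=0, fn=0))

    def test_scale_invariance(self):
        base = ConfusionCounts(3, 1, tn=7, fn=2)
        for s in (2, 5):
            scaled = ConfusionCounts(3 * s, 1 * s, tn=7 * s, fn=2 * s)
            assert ndr(scaled) == pytest.approx(ndr(base))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 1, 1)


class TestQualityLabel:
    @pytest.mark.parametrize("value,level,expected", [
        (0.69, "slice2D", "bad"),
        (0.70, "slice2D", "good"),
        (0.84, "subject3D", "bad"),
        (0.85, "subject3D", "good"),
        (0.0, "slice2D", "bad"),
        (1.0, "subject3D", "good"),
    ])
    def test_cutoffs(self, value, level, expected):
        assert label_quality(value, level).value == expected

    def test_monotone_step(self):
        grid = np.linspace(0, 1, 101)
        flags = [label_quality(v, QualityLevel.slice2D).is_good for v in grid]
        assert flags == sorted(flags)  # once good, always good

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_quality(1.2, "slice2D")

    def test_cutoff_override(self):
        assert label_quality(0.6, "slice2D", cutoff=0.5).value == "good"


class TestStackSlices:
    def test_perfect_stack(self):
        sl = np.zeros((8, 8), bool)
        sl[2:6, 2:6] = True
        stacked, spacing = stack_slices([sl] * 5, z_spacing=8.0)
        assert stacked.shape == (5, 8, 8)
        assert spacing == (8.0, 1.0, 1.0)
        assert dsc(stacked, np.stack([sl] * 5)) == 1.0

    def test_lost_apical_slice_barely_moves_3d_dice(self):
        """An emptied apical slice holding ~2% of the volume leaves 3D DSC ~0.99."""
        slices = []
        for k in range(10):
            sl = np.zeros((64, 64), bool)
            r = 20 if k < 9 else 3  # tiny apical cap
            yy, xx = np.ogrid[:64, :64]
            sl[(yy - 32) ** 2 + (xx - 32) ** 2 <= r ** 2] = True
            slices.append(sl)
        gt, _ = stack_slices(slices, 8.0)
        frac_apical = slices[-1].sum() / gt.sum()
        assert frac_apical < 0.02
        degraded = list(slices)
        degraded[-1] = np.zeros((64, 64), bool)
        deg, _ = stack_slices(degraded, 8.0)
        d = dsc(deg, gt)
        assert d == pytest.approx(2 * (1 - frac_apical) / (2 - frac_apical), abs=1e-12)
        assert d > 0.99

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stack_slices([], 8.0)

    def test_heterogeneous_shapes_rejected(self):
        with pytest.raises(ValueError, match="heterogeneous"):
            stack_slices([np.zeros((4, 4), bool), np.zeros((5, 5), bool)], 8.0)
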