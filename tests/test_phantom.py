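"""Phantom geometry, perturbation grading and dataset bookkeeping."""

import numpy as np
import pytest

from cineqc.core_metrics import dsc
from cineqc.phantom import (
    PERTURBATION_MODES,
    PerturbationSpec,
    PhantomParams,
    build_qc_dataset,
    calibrate_severity,
    generate_cohort,
    generate_phantom,
    perturb_mask,
)


class TestGeneratePhantom:
    def test_deterministic_from_seed(self):
        p = PhantomParams(seed=5)
        i1, l1 = generate_phantom(p)
        i2, l2 = generate_phantom(p)
        assert np.array_equal(i1.grid, i2.grid)
        assert np.array_equal(l1.grid, l2.grid)

    def test_mid_stack_slice_has_all_structures(self, phantom_labels):
        mid = phantom_labels.grid[phantom_labels.grid.shape[0] // 2]
        assert {1, 2, 3} <= set(np.unique(mid))

    def test_annulus_encloses_cavity(self, phantom_labels):
        """Exhaustive 4-neighbour check: LVC touches only LVC or MYO."""
        g = phantom_labels.grid
        lvc = g == 3
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            shifted = np.roll(g, (0, dr, dc), axis=(0, 1, 2))
            neighbours = shifted[lvc]
            assert set(np.unique(neighbours)) <= {2, 3}

    def test_radii_shrink_base_to_apex(self, phantom_labels):
        areas = [int((sl == 3).sum()) for sl in phantom_labels.grid]
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError, match="annulus"):
            generate_phantom(PhantomParams(myo_thickness_mm=0.5))

    def test_out_of_range_acquisition_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(n_slices=4)
        with pytest.raises(ValueError):
            PhantomParams(z_spacing_mm=12.0)

    def test_cohort_mixes_presets_and_is_deterministic(self):
        c1 = generate_cohort(6, seed=3)
        c2 = generate_cohort(6, seed=3)
        assert [p.preset for p, _, _ in c1] == [p.preset for p, _, _ in c2]
        assert all(np.array_equal(a[1].grid, b[1].grid) for a, b in zip(c1, c2))


class TestPerturbMask:
    @pytest.mark.parametrize("mode", [m for m in PERTURBATION_MODES if m != "empty"])
    def test_severity_zero_is_identity(self, phantom_labels, mode):
        spec = PerturbationSpec(mode=mode, severity=0.0, seed=1)
        out = perturb_mask(phantom_labels, spec, "LVC")
        assert dsc(out.structure_mask("LVC"), phantom_labels.structure_mask("LVC")) == 1.0

    def test_empty_mode_removes_structure(self, phantom_labels):
        out = perturb_mask(phantom_labels, PerturbationSpec("empty", 1.0), "MYO")
        assert not out.structure_mask("MYO").any()
        assert dsc(out.structure_mask("MYO"), phantom_labels.structure_mask("MYO")) == 0.0

    def test_other_structures_untouched_by_erosion(self, phantom_labels):
        out = perturb_mask(phantom_labels, PerturbationSpec("erode", 0.5, seed=2), "LVC")
        assert np.array_equal(out.structure_mask("RVC"), phantom_labels.structure_mask("RVC"))
        assert np.array_equal(out.structure_mask("MYO"), phantom_labels.structure_mask("MYO"))
        # eroded LVC pixels become background, nothing else changes
        changed = out.grid != phantom_labels.grid
        assert np.all(phantom_labels.grid[changed] == 3)
        assert np.all(out.grid[changed] == 0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            PerturbationSpec(mode="smudge", severity=0.5)

    @pytest.mark.parametrize("mode", [m for m in PERTURBATION_MODES if m != "empty"])
    def test_mean_dice_decreases_with_severity(self, phantom_labels, mode):
        """Monte-Carlo: heavier degradation gives lower mean Dice (5 seeds here)."""
        gt = phantom_labels.structure_mask("LVC")

        def mean_dsc(sev):
            vals = []
            for seed in range(5):
                out = perturb_mask(phantom_labels, PerturbationSpec(mode, sev, seed), "LVC")
                vals.append(dsc(out.structure_mask("LVC"), gt))
            return float(np.mean(vals))

        assert mean_dsc(0.8) < mean_dsc(0.2)


class TestCalibrateSeverity:
    def test_target_one_means_no_perturbation(self, phantom_labels):
        spec = calibrate_severity(phantom_labels, "LVC", 1.0, "erode")
        assert spec.severity == 0.0 and spec.realized_dsc == 1.0

    @pytest.mark.parametrize("mode", ["erode", "dilate", "boundary_jitter", "translate"])
    def test_hits_target_within_tolerance(self, phantom_labels, mode):
        spec = calibrate_severity(phantom_labels, "LVC", 0.7, mode, seed=4)
        realized = spec.realized_dsc
        assert 0.65 <= realized <= 0.75

    def test_unreachable_target_names_range(self, phantom_labels):
        with pytest.raises(ValueError, match="achievable range"):
            calibrate_severity(phantom_labels, "LVC", 0.0, "dilate")

    def test_recorded_dsc_matches_replay(self, phantom_labels):
        spec = calibrate_severity(phantom_labels, "MYO", 0.6, "erode", seed=9)
        out = perturb_mask(phantom_labels, spec, "MYO")
        replay = dsc(out.structure_mask("MYO"), phantom_labels.structure_mask("MYO"))
        assert replay == pytest.approx(spec.realized_dsc, abs=1e-12)


@pytest.fixture(scope="module")
def small():
    cohort = generate_cohort(2, seed=8)
    return cohort, build_qc_dataset(cohort, n_variants=3, seed=8)


class TestBuildQcDataset:
    def test_bookkeeping(self, small):
        cohort, (segs, index) = small
        three_d = index[index["level"] == "3D"]
        # subjects x variants records per structure
        for s in ("RVC", "MYO", "LVC"):
            assert len(three_d[three_d["structure"] == s]) == 2 * 3
        assert len(segs) == 2 * 3 * 3

    def test_stored_dsc_matches_recomputation(self, small):
        cohort, (segs, index) = small
        for (si, structure, v), pert in segs.items():
            gt = cohort[si][2].structure_mask(structure)
            row = index[(index.subject == si) & (index.structure == structure)
                        & (index.variant == v) & (index.level == "3D")]
            assert row["actual_dsc"].iloc[0] == pytest.approx(
                dsc(pert.structure_mask(structure), gt), abs=1e-12)

    def test_reproducible_from_seeds(self, small):
        cohort, (_, index) = small
        _, index2 = build_qc_dataset(cohort, n_variants=3, seed=8)
        assert index.equals(index2)

    def test_dice_spans_both_cutoffs(self, small):
        _, (_, index) = small
        d3 = index[index["level"] == "3D"]["actual_dsc"]
        d2 = index[(index["level"] == "2D") & ~index["empty_pair"]]["actual_dsc"]
        assert (d3 < 0.85).any() and (d3 >= 0.85).any()
        assert (d2 < 0.7).any() and (d2 >= 0.7).any()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            build_qc_dataset([], 4)


def test_drop_apical_hurts_2d_more_than_3d(phantom_labels):
    """Dropped apical slices barely move 3D Dice while their 2D Dice collapses."""
    spec = PerturbationSpec("drop_apical", severity=0.25, seed=0)
    out = perturb_mask(phantom_labels, spec, "LVC")
    gt = phantom_labels.structure_mask("LVC")
    pert = out.structure_mask("LVC")
    d3 = dsc(pert, gt)
    dropped = [k for k in range(gt.shape[0]) if gt[k].any() and not pert[k].any()]
    assert dropped, "expected at least one dropped apical slice"
    d2 = [dsc(pert[k], gt[k]) for k in dropped]
    assert max(d2) == 0.0
    assert d3 > 0.9
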