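"""Phantom generator: geometry, volume allocation, truth consistency."""

import math
from dataclasses import replace

import numpy as np
import pytest

from pulmoquant.phantom import (
    CohortSpec,
    InfeasibleVesselVolumeError,
    LungGeometry,
    PhantomError,
    PhantomSpec,
    VesselTree,
    _rasterize_tree,
    draw_cohort_specs,
    generate_cohort,
    generate_vessel_tree,
    rasterize_phantom,
)

# Small enough that even apical_fraction 0 or 1 (one lobe pair carrying
# everything) stays feasible on the 64^3 grid.
SMALL = PhantomSpec(grid_shape=(64, 64, 64), spacing_mm=(2.0, 2.0, 2.0),
                    target_vessel_volume_cm3=6.0, seed=3)


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"apical_fraction": 1.5},
        {"oligemia_fraction": -0.1},
        {"spacing_mm": (1.0, 0.0, 1.0)},
        {"oligemia_shift_hu": 10.0},
        {"n_tree_generations": 0},
        {"target_vessel_volume_cm3": -5.0},
        # vessels not separable from parenchyma by 5 SD
        {"vessel_hu": -700.0},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(PhantomError):
            PhantomSpec(**kwargs)


class TestVesselTree:
    def test_apical_fraction_zero_uses_only_lower_lobes(self):
        tree = generate_vessel_tree(replace(SMALL, apical_fraction=0.0))
        assert set(tree.lobe_of_segment) == {"RLL", "LLL"}

    def test_apical_fraction_one_uses_only_upper_lobes(self):
        tree = generate_vessel_tree(replace(SMALL, apical_fraction=1.0))
        assert set(tree.lobe_of_segment) == {"RUL", "LUL"}

    def test_radii_positive_and_murray_decreasing(self, unit_tree):
        radii = [r for *_, r in unit_tree.segments]
        assert all(r > 0 for r in radii)
        # within each lobe the root is the thickest and children shrink by 2^(-1/3)
        by_lobe = {}
        for (a, b, r), lobe in zip(unit_tree.segments, unit_tree.lobe_of_segment):
            by_lobe.setdefault(lobe, []).append(r)
        for rs in by_lobe.values():
            uniq = sorted(set(np.round(rs, 9)), reverse=True)
            for parent, child in zip(uniq, uniq[1:]):
                assert child <= parent
                assert child / parent == pytest.approx(2 ** (-1 / 3), rel=1e-6)

    def test_segment_midpoints_inside_assigned_lobe(self, unit_tree):
        geom = LungGeometry(PhantomSpec(grid_shape=(96,) * 3,
                                        spacing_mm=(1.8,) * 3).extent_mm)
        for (a, b, _), lobe in zip(unit_tree.segments, unit_tree.lobe_of_segment):
            assert geom.in_lobe(0.5 * (a + b), lobe)

    def test_upper_lobe_allocation_matches_apical_fraction(self):
        tree = generate_vessel_tree(replace(SMALL, apical_fraction=0.6))
        upper = sum(math.pi * r * r * np.linalg.norm(b - a)
                    for (a, b, r), lobe in zip(tree.segments, tree.lobe_of_segment)
                    if lobe in ("RUL", "LUL"))
        total = tree.analytic_volume_mm3()
        assert upper / total == pytest.approx(0.6, abs=0.06)  # +-10% of target

    def test_infeasible_volume_raises(self):
        bad = replace(SMALL, target_vessel_volume_cm3=500.0)
        with pytest.raises(InfeasibleVesselVolumeError):
            generate_vessel_tree(bad)


class TestRasterization:
    def test_single_cylinder_volume_matches_analytic(self):
        # radius 3 mm, length 20 mm -> pi*9*20 ~ 565.5 mm3 on a 1 mm grid
        a = np.array([20.0, 20.0, 10.0])
        b = np.array([20.0, 20.0, 30.0])
        tree = VesselTree(segments=[(a, b, 3.0)], lobe_of_segment=["RUL"])
        mask = _rasterize_tree(tree, (40, 40, 40), (1.0, 1.0, 1.0))
        analytic = math.pi * 9.0 * 20.0
        assert mask.sum() == pytest.approx(analytic, rel=0.15)

    def test_rasterized_tree_volume_within_15pct_of_analytic(self):
        # at working resolution all radii are >= 2 voxels, where the
        # voxelization-fidelity guarantee applies
        spec = PhantomSpec(seed=7)
        tree = generate_vessel_tree(spec)
        assert min(r for *_, r in tree.segments) >= 2 * max(spec.spacing_mm)
        mask = _rasterize_tree(tree, spec.grid_shape, spec.spacing_mm)
        analytic = tree.analytic_volume_mm3()
        raster = mask.sum() * spec.extent_mm.prod() / np.prod(spec.grid_shape)
        assert raster == pytest.approx(analytic, rel=0.15)

    def test_deterministic_given_seed(self):
        ct1, t1 = rasterize_phantom(SMALL)
        ct2, t2 = rasterize_phantom(SMALL)
        assert np.array_equal(ct1.voxels, ct2.voxels)
        assert np.array_equal(t1.vessel_mask, t2.vessel_mask)
        assert t1.vessel_volume_per_lobe_cm3 == t2.vessel_volume_per_lobe_cm3

    def test_truth_masks_consistent(self, unit_phantom):
        spec, ct, truth = unit_phantom
        assert not np.any(truth.vessel_mask & ~truth.lung_mask)
        assert not np.any(truth.oligemia_mask & ~truth.lung_mask)
        assert not np.any(truth.oligemia_mask & truth.vessel_mask)
        labeled = truth.lobe_labels.labels > 0
        assert np.array_equal(labeled, truth.lung_mask)

    def test_truth_volume_conservation_exact(self, unit_phantom):
        spec, ct, truth = unit_phantom
        total = sum(truth.vessel_volume_per_lobe_cm3.values())
        by_count = truth.vessel_mask.sum() * ct.voxel_volume_mm3 / 1000.0
        assert total == pytest.approx(by_count, abs=1e-12)

    def test_target_volume_reached(self):
        spec = PhantomSpec(target_vessel_volume_cm3=60.0, seed=11)
        _, truth = rasterize_phantom(spec)
        assert 51.0 <= truth.total_vessel_volume_cm3 <= 69.0

    def test_no_oligemia_means_empty_mask(self, unit_phantom):
        _, _, truth = unit_phantom
        assert truth.oligemia_mask.sum() == 0

    def test_parenchyma_mean_without_noise(self):
        spec = replace(SMALL, noise_sd_hu=0.0, oligemia_fraction=0.0)
        ct, truth = rasterize_phantom(spec)
        parenchyma = truth.lung_mask & ~truth.vessel_mask
        assert ct.voxels[parenchyma].mean() == pytest.approx(
            spec.parenchyma_mean_hu, abs=1.0)

    def test_oligemia_fraction_approximately_reached(self):
        spec = replace(SMALL, oligemia_fraction=0.15)
        ct, truth = rasterize_phantom(spec)
        parenchyma = (truth.lung_mask & ~truth.vessel_mask).sum()
        frac = truth.oligemia_mask.sum() / parenchyma
        assert 0.10 <= frac <= 0.25

    def test_grid_too_small_raises(self):
        with pytest.raises(PhantomError):
            rasterize_phantom(PhantomSpec(grid_shape=(8, 8, 8)))

    def test_upper_fraction_monotone_in_apical_fraction(self):
        fracs = []
        for af in (0.0, 0.25, 0.5, 0.75, 1.0):
            _, truth = rasterize_phantom(replace(SMALL, apical_fraction=af))
            v = truth.vessel_volume_per_lobe_cm3
            upper = v["RUL"] + v["LUL"]
            fracs.append(upper / truth.total_vessel_volume_cm3)
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] == 0.0 and fracs[-1] == 1.0


class TestCohort:
    def test_all_control_when_n_ph_zero(self):
        cohort = draw_cohort_specs(CohortSpec(n_control=3, n_ph=0, seed=1), SMALL)
        assert [g for _, g in cohort] == ["control"] * 3

    def test_cohort_deterministic(self):
        cs = CohortSpec(n_control=2, n_ph=2, seed=9)
        c1 = generate_cohort(cs, SMALL)
        c2 = generate_cohort(cs, SMALL)
        for (ct1, t1, g1), (ct2, t2, g2) in zip(c1, c2):
            assert g1 == g2
            assert np.array_equal(ct1.voxels, ct2.voxels)

    def test_ph_arm_has_higher_upper_lobe_truth_fraction(self):
        cs = CohortSpec(n_control=8, n_ph=8, seed=5)
        means = {"control": [], "PH": []}
        for spec, group in draw_cohort_specs(cs, SMALL):
            tree = generate_vessel_tree(spec)
            upper = sum(math.pi * r * r * np.linalg.norm(b - a)
                        for (a, b, r), lobe in zip(tree.segments, tree.lobe_of_segment)
                        if lobe in ("RUL", "LUL"))
            means[group].append(upper / tree.analytic_volume_mm3())
        assert np.mean(means["PH"]) > np.mean(means["control"])

    def test_draws_truncated_to_unit_interval(self):
        cs = CohortSpec(n_control=0, n_ph=30,
                        ph_apical_fraction_dist=(0.9, 0.5),
                        ph_oligemia_fraction_dist=(0.05, 0.3), seed=2)
        for spec, _ in draw_cohort_specs(cs, SMALL):
            assert 0.0 <= spec.apical_fraction <= 1.0
            assert 0.0 <= spec.oligemia_fraction <= 1.0
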