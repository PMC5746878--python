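"""Vessel detection: threshold rule, component filter, lobar volumes."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import volume_filtered_voxels
from pulmoquant.imaging import LOBE_CODES, CTVolume, LobeLabelMap, SubjectRecord
from pulmoquant.lungs import LungMask
from pulmoquant.phantom import PhantomSpec, rasterize_phantom
from pulmoquant.vessels import (
    EmptyMaskError,
    PipelineConfig,
    body_size_correction_factor,
    bsa_dubois_m2,
    compute_threshold,
    segment_vessels,
    vessel_volume_per_lobe,
)

CFG = PipelineConfig()


def full_mask_volume(values, spacing=(2.0, 2.0, 2.0)):
    """Wrap an HU array as a CTVolume with an all-lung mask."""
    ct = CTVolume(np.asarray(values, dtype=np.float32), spacing)
    mask = np.ones(ct.shape, dtype=bool)
    return ct, LungMask(mask=mask, left=np.zeros_like(mask), right=mask)


class TestComputeThreshold:
    def test_normal_lung_uses_standard_threshold(self):
        # control-like mean density around -652 HU lies inside the trigger band
        ct, mask = full_mask_volume(np.full((8, 8, 8), -652.0))
        thr, adaptive = compute_threshold(ct, mask, CFG)
        assert thr == -500.0 and adaptive is False

    def test_dense_lung_mode_plus_offset_clamped_high(self):
        ct, mask = full_mask_volume(np.full((8, 8, 8), -400.0))
        thr, adaptive = compute_threshold(ct, mask, CFG)
        # mode -400 + 360 = -40, clamped to -200
        assert thr == -200.0 and adaptive is True

    def test_lucent_lung_mode_plus_offset_within_clamp(self):
        ct, mask = full_mask_volume(np.full((8, 8, 8), -900.0))
        thr, adaptive = compute_threshold(ct, mask, CFG)
        assert thr == -540.0 and adaptive is True

    def test_mode_ties_break_toward_lower_hu(self):
        vals = np.full((4, 4, 4), -950.0)
        vals.ravel()[:32] = -940.0  # two equally common values
        ct, mask = full_mask_volume(vals)
        thr, adaptive = compute_threshold(ct, mask, CFG)
        assert adaptive is True and thr == pytest.approx(-950.0 + 360.0)

    def test_empty_mask_rejected(self):
        ct = CTVolume(np.full((4, 4, 4), -700.0), (1, 1, 1))
        mask = LungMask.__new__(LungMask)  # bypass the non-empty check
        mask.mask = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(EmptyMaskError):
            compute_threshold(ct, mask, CFG)


class TestComponentFilter:
    def test_100mm3_rule_on_hand_built_grid(self):
        # 2 mm voxels = 8 mm3 each: 13 voxels = 104 mm3 kept,
        # 12 voxels = 96 mm3 rejected
        hu = np.full((10, 10, 10), -850.0)
        hu[1, 1, 0:7] = 150.0
        hu[2, 2, 0:6] = 150.0  # 13 voxels, 26-connected diagonally
        hu[7, 7, 0:6] = 150.0
        hu[8, 8, 0:6] = 150.0  # 12 voxels
        ct, mask = full_mask_volume(hu, (2.0, 2.0, 2.0))
        seg = segment_vessels(ct, mask, CFG, threshold_hu=-500.0)
        assert len(seg.components) == 1
        assert seg.components[0].voxel_count == 13
        assert seg.total_volume_cm3 == pytest.approx(0.104)

    def test_all_below_threshold_gives_empty_valid_result(self):
        ct, mask = full_mask_volume(np.full((6, 6, 6), -850.0))
        seg = segment_vessels(ct, mask, CFG, threshold_hu=-500.0)
        assert seg.vessel_mask.sum() == 0 and seg.components == []

    def test_threshold_comparison_is_inclusive(self):
        hu = np.full((8, 8, 8), -850.0)
        hu[2:6, 2:6, 2:6] = -500.0  # exactly at the threshold
        ct, mask = full_mask_volume(hu)
        seg = segment_vessels(ct, mask, CFG, threshold_hu=-500.0)
        assert seg.vessel_mask.sum() == 64

    def test_filter_idempotent(self, unit_phantom):
        _, ct, truth = unit_phantom
        mask = LungMask(mask=truth.lung_mask,
                        left=np.zeros_like(truth.lung_mask), right=truth.lung_mask)
        seg1 = segment_vessels(ct, mask, CFG)
        ct2 = CTVolume(np.where(seg1.vessel_mask, 150.0, -850.0).astype(np.float32),
                       ct.spacing_mm)
        seg2 = segment_vessels(ct2, mask, CFG, threshold_hu=-500.0)
        assert np.array_equal(seg1.vessel_mask, seg2.vessel_mask)

    def test_vessel_volume_monotone_in_threshold(self, unit_phantom):
        _, ct, truth = unit_phantom
        mask = LungMask(mask=truth.lung_mask,
                        left=np.zeros_like(truth.lung_mask), right=truth.lung_mask)
        vols = [segment_vessels(ct, mask, CFG, threshold_hu=t).total_volume_cm3
                for t in (-700.0, -500.0, -300.0, 0.0, 140.0)]
        assert all(b <= a for a, b in zip(vols, vols[1:]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), connectivity=st.sampled_from([6, 26]))
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(5, 11, 3))
        grid = rng.random(shape) < rng.uniform(0.15, 0.5)
        spacing = float(rng.choice([1.7, 2.0, 2.4]))
        hu = np.where(grid, 150.0, -850.0)
        ct, mask = full_mask_volume(hu, (spacing,) * 3)
        cfg = replace(CFG, connectivity=connectivity)
        seg = segment_vessels(ct, mask, cfg, threshold_hu=-500.0)
        expected = volume_filtered_voxels(grid, connectivity, spacing**3, 100.0)
        got = set(zip(*np.nonzero(seg.vessel_mask)))
        assert got == expected


class TestBodySizeCorrection:
    def test_default_mode_and_missing_biometrics_give_unity(self):
        rec = SubjectRecord("s1", "control")
        assert body_size_correction_factor(rec, CFG) == 1.0
        cfg = replace(CFG, body_size_correction="bsa")
        assert body_size_correction_factor(rec, cfg) == 1.0

    def test_reference_bsa_gives_unity(self):
        # solve DuBois for a height/weight pair with BSA exactly 1.73
        height = 170.0
        weight = (1.73 / (0.007184 * height**0.725)) ** (1 / 0.425)
        rec = SubjectRecord("s1", "control", height_cm=height, weight_kg=weight)
        cfg = replace(CFG, body_size_correction="bsa")
        assert body_size_correction_factor(rec, cfg) == pytest.approx(1.0, abs=1e-12)

    def test_dubois_formula_for_80kg_180cm(self):
        rec = SubjectRecord("s1", "PH", height_cm=180.0, weight_kg=80.0, mpap_mmhg=40)
        cfg = replace(CFG, body_size_correction="bsa")
        expected = 1.73 / (0.007184 * 80.0**0.425 * 180.0**0.725)
        assert body_size_correction_factor(rec, cfg) == pytest.approx(expected, rel=1e-12)
        assert bsa_dubois_m2(80.0, 180.0) == pytest.approx(1.9964210, rel=1e-6)

    def test_nonpositive_biometrics_rejected(self):
        rec = SubjectRecord("s1", "control", height_cm=-170.0, weight_kg=70.0)
        cfg = replace(CFG, body_size_correction="bsa")
        with pytest.raises(ValueError):
            body_size_correction_factor(rec, cfg)


class TestVesselVolumePerLobe:
    def test_empty_mask_gives_zero_everywhere(self):
        ct, mask = full_mask_volume(np.full((6, 6, 6), -850.0))
        seg = segment_vessels(ct, mask, CFG, threshold_hu=-500.0)
        lobes = LobeLabelMap(labels=np.ones((6, 6, 6), dtype=np.int16))
        vols = vessel_volume_per_lobe(seg, lobes, ct.spacing_mm)
        assert all(v == 0.0 for v in vols.values())

    def test_conservation_with_unassigned(self, unit_phantom):
        _, ct, truth = unit_phantom
        mask = LungMask(mask=truth.lung_mask,
                        left=np.zeros_like(truth.lung_mask), right=truth.lung_mask)
        seg = segment_vessels(ct, mask, CFG)
        labels = truth.lobe_labels.labels.copy()
        labels[:, :, : labels.shape[2] // 2] = 0  # unlabel the caudal half
        vols = vessel_volume_per_lobe(seg, LobeLabelMap(labels=labels), ct.spacing_mm)
        assert sum(vols.values()) == pytest.approx(seg.total_volume_cm3, abs=1e-9)
        assert vols["unassigned"] > 0

    def test_apical_phantom_concentrates_volume_in_upper_lobes(self):
        spec = PhantomSpec(grid_shape=(64,) * 3, spacing_mm=(2.0,) * 3,
                           target_vessel_volume_cm3=6.0, apical_fraction=1.0, seed=4)
        ct, truth = rasterize_phantom(spec)
        mask = LungMask(mask=truth.lung_mask,
                        left=np.zeros_like(truth.lung_mask), right=truth.lung_mask)
        seg = segment_vessels(ct, mask, CFG)
        vols = vessel_volume_per_lobe(seg, truth.lobe_labels, ct.spacing_mm)
        lower = vols["RLL"] + vols["LLL"]
        assert lower < 0.05 * seg.total_volume_cm3

    def test_grid_mismatch_rejected(self, unit_phantom):
        _, ct, truth = unit_phantom
        mask = LungMask(mask=truth.lung_mask,
                        left=np.zeros_like(truth.lung_mask), right=truth.lung_mask)
        seg = segment_vessels(ct, mask, CFG)
        with pytest.raises(ValueError, match="grid"):
            vessel_volume_per_lobe(
                seg, LobeLabelMap(labels=np.zeros((5, 5, 5), dtype=np.int16)),
                ct.spacing_mm)

    def test_component_majority_vote_with_cranial_tie_break(self):
        hu = np.full((10, 10, 10), -850.0)
        hu[5, 5, 2:8] = 150.0  # 6 voxels spanning two lobes, 3 in each
        ct, mask = full_mask_volume(hu, (3.0, 3.0, 3.0))
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels[:, :, :5] = LOBE_CODES["RLL"]
        labels[:, :, 5:] = LOBE_CODES["RUL"]
        seg = segment_vessels(ct, mask, CFG, lobes=LobeLabelMap(labels=labels),
                              threshold_hu=-500.0)
        assert len(seg.components) == 1
        # 3 voxels in RLL, 3 in RUL: tie resolved toward the cranial lobe
        assert seg.components[0].lobe == "RUL"
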