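"""Thresholding, region statistics, the adaptive rule table, and closing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from htseg import (
    BinaryMask,
    CTVolume,
    PhantomSpec,
    ROIBox,
    RuleTable,
    ThresholdWindow,
    adaptive_segment,
    classify_and_update,
    close_mask,
    make_head_phantom,
    region_stats,
    threshold_segment,
)
from htseg.adaptive_segmentation import DEFAULT_RULES, OVER, UNDER, WELL

from conftest import SPACING, flat_volume, full_brain, full_roi

W5080 = ThresholdWindow(50.0, 80.0)


class TestThresholdSegment:
    def test_uniform_interior_fully_selected(self):
        vol = flat_volume(value=65.0)
        mask = threshold_segment(vol, full_roi(vol), full_brain(vol), W5080)
        assert mask.voxels.all()

    def test_below_low_bound_empty(self):
        vol = flat_volume(value=49.0)
        assert threshold_segment(vol, full_roi(vol), full_brain(vol), W5080).count() == 0

    def test_bounds_inclusive_both_ends(self):
        vox = np.full((1, 2, 2), 0.0, np.float32)
        vox[0] = [[45.0, 50.0], [80.0, 81.0]]
        vol = CTVolume(vox, SPACING)
        mask = threshold_segment(vol, full_roi(vol), full_brain(vol), W5080)
        np.testing.assert_array_equal(mask.voxels[0], [[False, True], [True, False]])

    def test_confined_to_roi_and_brain(self, rng):
        vol = CTVolume(rng.uniform(40, 90, (4, 16, 16)).astype(np.float32), SPACING)
        roi = ROIBox(1, 3, 4, 12, 4, 12)
        brain_vox = rng.random(vol.shape) < 0.7
        brain = full_brain(vol)
        brain.mask.voxels[:] = brain_vox
        mask = threshold_segment(vol, roi, brain, W5080)
        assert not (mask.voxels & ~roi.support(vol.shape)).any()
        assert not (mask.voxels & ~brain_vox).any()

    def test_roi_out_of_bounds(self):
        vol = flat_volume()
        with pytest.raises(IndexError):
            threshold_segment(vol, ROIBox(0, 99, 0, 4, 0, 4), full_brain(vol), W5080)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**32 - 1), st.floats(0, 10), st.floats(0, 10))
    def test_wider_window_gives_superset(self, seed, grow_lo, grow_hi):
        rng = np.random.default_rng(seed)
        vol = CTVolume(rng.uniform(20, 100, (3, 12, 12)).astype(np.float32), SPACING)
        inner = threshold_segment(vol, full_roi(vol), full_brain(vol), W5080)
        wider = ThresholdWindow(50.0 - grow_lo, 80.0 + grow_hi)
        outer = threshold_segment(vol, full_roi(vol), full_brain(vol), wider)
        assert (outer.voxels | inner.voxels).sum() == outer.voxels.sum()


class TestRegionStats:
    def test_constant_region(self):
        vol = flat_volume(value=60.0)
        stats = region_stats(vol, BinaryMask(np.ones(vol.shape, bool), SPACING))
        assert stats.mean == 60.0 and stats.sd == 0.0

    def test_population_sd(self):
        vox = np.array([[[50.0, 70.0]]], np.float32)
        vol = CTVolume(vox, SPACING)
        stats = region_stats(vol, BinaryMask(np.ones(vol.shape, bool), SPACING))
        assert stats.mean == pytest.approx(60.0)
        assert stats.sd == pytest.approx(10.0)  # population, not sample
        assert stats.voxel_count == 2

    def test_empty_mask_routes_to_zero_sd(self):
        vol = flat_volume()
        stats = region_stats(vol, BinaryMask(np.zeros(vol.shape, bool), SPACING))
        assert stats.voxel_count == 0 and stats.sd == 0.0 and np.isnan(stats.mean)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            region_stats(flat_volume(), BinaryMask(np.ones((2, 2, 2), bool), SPACING))


class TestRuleTable:
    @pytest.mark.parametrize(
        "sd,label,window",
        [
            (0.0, UNDER, (35.0, 65.0)),
            (1.0, UNDER, (40.0, 70.0)),
            (2.3, UNDER, (40.0, 70.0)),
            (2.31, UNDER, (45.0, 75.0)),
            (6.0, UNDER, (45.0, 75.0)),
            (6.01, WELL, (50.0, 80.0)),
            (8.0, WELL, (50.0, 80.0)),
            (11.0, WELL, (50.0, 80.0)),
            (11.000001, OVER, (55.0, 85.0)),
            (50.0, OVER, (55.0, 85.0)),
        ],
    )
    def test_rule_rows(self, sd, label, window):
        got_label, got_window = classify_and_update(sd)
        assert got_label == label
        assert got_window.as_tuple() == window

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            classify_and_update(-0.1)

    @settings(deadline=None, max_examples=200)
    @given(st.floats(0.0, 100.0, allow_nan=False))
    def test_exactly_one_rule_applies(self, sd):
        # partition: membership over all rows sums to one
        hits = 0
        if sd == 0.0:
            hits += 1
        prev = 0.0
        for bound in (2.3, 6.0, 11.0):
            if prev < sd <= bound:
                hits += 1
            prev = bound
        if sd > 11.0:
            hits += 1
        assert hits == 1
        label, window = classify_and_update(sd)  # never raises on sd >= 0
        assert window.width == 30.0

    def test_all_windows_30_hu_wide(self):
        assert DEFAULT_RULES.initial.width == 30.0
        for _, _, window in DEFAULT_RULES.rows:
            assert window.width == 30.0

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text(
            "initial: [50, 80]\n"
            "rules:\n"
            "  - {sd_max: 0, label: under-segmented, window: [35, 65]}\n"
            "  - {sd_max: 2.3, label: under-segmented, window: [40, 70]}\n"
            "  - {sd_max: 6, label: under-segmented, window: [45, 75]}\n"
            "  - {sd_max: 11, label: well-segmented, window: [50, 80]}\n"
            "  - {sd_max: .inf, label: over-segmented, window: [55, 85]}\n"
        )
        rules = RuleTable.from_yaml(path)
        for sd in (0.0, 1.0, 4.0, 8.0, 20.0):
            assert rules.classify(sd) == DEFAULT_RULES.classify(sd)


def brute_force_closing(mask2d: np.ndarray, size: int) -> np.ndarray:
    """Independent oracle: a pixel is off after closing iff some size x size
    window covering it contains no foreground (closing = complement of the
    opening of the complement, placements enumerated explicitly)."""
    h, w = mask2d.shape
    pad = size
    padded = np.pad(mask2d, pad, mode="constant", constant_values=False)
    off = np.zeros_like(padded)
    for i in range(padded.shape[0] - size + 1):
        for j in range(padded.shape[1] - size + 1):
            if not padded[i : i + size, j : j + size].any():
                off[i : i + size, j : j + size] = True
    return (~off)[pad:-pad, pad:-pad]


class TestCloseMask:
    def test_fills_interior_hole(self):
        vox = np.zeros((1, 16, 16), bool)
        vox[0, 4:12, 4:12] = True
        vox[0, 7:9, 7:9] = False  # 2x2 hole < 4x4 kernel
        closed = close_mask(BinaryMask(vox, SPACING), kernel_size=4)
        assert closed.voxels[0, 7:9, 7:9].all()

    def test_empty_mask_stays_empty(self):
        m = BinaryMask(np.zeros((2, 8, 8), bool), SPACING)
        assert close_mask(m, 4).count() == 0

    def test_extensive_and_idempotent_on_random_masks(self, rng):
        for _ in range(10):
            vox = rng.random((2, 20, 20)) < 0.35
            m = BinaryMask(vox, SPACING)
            once = close_mask(m, 4)
            assert (once.voxels | vox).sum() == once.voxels.sum()  # superset
            twice = close_mask(once, 4)
            np.testing.assert_array_equal(once.voxels, twice.voxels)

    def test_matches_brute_force_placement_oracle(self, rng):
        for _ in range(5):
            vox = rng.random((1, 18, 18)) < 0.3
            got = close_mask(BinaryMask(vox, SPACING), 4).voxels[0]
            np.testing.assert_array_equal(got, brute_force_closing(vox[0], 4))

    def test_does_not_cross_roi_bounds(self, rng):
        vox = rng.random((2, 20, 20)) < 0.4
        roi = ROIBox(0, 2, 5, 15, 5, 15)
        vox &= roi.support((2, 20, 20))
        closed = close_mask(BinaryMask(vox, SPACING), 4, roi=roi)
        assert not (closed.voxels & ~roi.support((2, 20, 20))).any()


class TestAdaptiveSegment:
    def test_well_segmented_branch_on_matched_lesion(self, clean_phantom):
        res = adaptive_segment(clean_phantom.volume, clean_phantom.roi, clean_phantom.brain)
        assert res.label == WELL
        assert res.final_window.as_tuple() == (50.0, 80.0)
        assert 6.0 < res.stats.sd <= 11.0

    def test_zero_sd_branch_recovers_faint_lesion(self):
        """A constant 47 HU lesion is invisible at 50-80; the empty initial
        pass routes to the SD=0 rule (35-65) and the second pass finds it."""
        spec = PhantomSpec(
            shape=(12, 64, 64), lesion_mean=47.0, lesion_sd=0.0, lesion_target_ml=3.0,
            noise_sd=0.0, blur_sigma=0.0, seed=5,
        )
        case = make_head_phantom(spec)
        res = adaptive_segment(case.volume, case.roi, case.brain)
        assert res.stats.voxel_count == 0 and res.label == UNDER
        assert res.final_window.as_tuple() == (35.0, 65.0)
        assert (res.mask.voxels & case.gt.voxels).sum() >= 0.99 * case.gt.count()

    def test_pure_background_roi_yields_empty_mask(self):
        vol = flat_volume(value=30.0, shape=(4, 16, 16))
        res = adaptive_segment(vol, full_roi(vol), full_brain(vol))
        assert res.mask.count() == 0 and res.volume_ml == 0.0

    def test_mask_confined_to_roi_and_brain(self, noisy_phantom):
        case = noisy_phantom
        res = adaptive_segment(case.volume, case.roi, case.brain)
        allowed = case.roi.support(case.volume.shape) & case.brain.voxels
        assert not (res.mask.voxels & ~allowed).any()

    def test_global_mode_keeps_nominal_window(self, clean_phantom):
        res = adaptive_segment(
            clean_phantom.volume, clean_phantom.roi, clean_phantom.brain, adaptive=False
        )
        assert res.final_window.as_tuple() == (50.0, 80.0)

    def test_deterministic(self, noisy_phantom):
        a = adaptive_segment(noisy_phantom.volume, noisy_phantom.roi, noisy_phantom.brain)
        b = adaptive_segment(noisy_phantom.volume, noisy_phantom.roi, noisy_phantom.brain)
        np.testing.assert_array_equal(a.mask.voxels, b.mask.voxels)
        assert a.volume_ml == b.volume_ml
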