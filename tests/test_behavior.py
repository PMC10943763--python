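"""Behavioral element detectors, temporal filter, copulation promotion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flycourt import behavior as bh

from conftest import make_pose

MM_PER_PX = 0.05  # 11-mm arena across 220 px


class TestSinging:
    @pytest.mark.parametrize("tl,tr,expected", [
        (35.0, 5.0, True),
        (30.0, 30.0, False),   # strict inequality at the threshold
        (0.0, 0.0, False),
        (5.0, 31.0, True),     # either wing suffices
    ])
    def test_threshold_rule(self, tl, tr, expected):
        pose = make_pose(theta_l=tl, theta_r=tr)
        assert bh.detect_singing(pose) == expected

    @given(st.floats(0, 179), st.floats(0, 179))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_max_wing_angle(self, a, b):
        # increasing the larger wing angle never turns singing off
        lo = bh.detect_singing(make_pose(theta_l=a, theta_r=b))
        hi = bh.detect_singing(make_pose(theta_l=a + 1, theta_r=b + 1))
        assert hi or not lo


class TestOrientation:
    def _pair(self, female_at, heading=0.0):
        male = make_pose(centroid=(100.0, 100.0), heading_deg=heading,
                         head_dist=20.0)
        female = make_pose(centroid=female_at, heading_deg=180.0)
        return male, female

    def test_female_dead_ahead_at_half_radius(self):
        male, female = self._pair((100.0, 125.0))  # 25 px = 0.5 x 50-px radius
        assert bh.detect_orientation(male, female)

    def test_angular_offset_just_outside_sector(self):
        r = 30.0
        for off_deg, expected in ((9.0, True), (11.0, False)):
            col = 100 + r * np.cos(np.deg2rad(off_deg))
            row = 100 - r * np.sin(np.deg2rad(off_deg))
            male, female = self._pair((row, col))
            assert bh.detect_orientation(male, female) == expected

    def test_beyond_extended_vector_length(self):
        male, female = self._pair((100.0, 155.0))  # 55 px > 2.5 x 20
        assert not bh.detect_orientation(male, female)
        near, female2 = self._pair((100.0, 145.0))  # 45 px < 50
        assert bh.detect_orientation(near, female2)

    def test_degenerate_heading_is_false(self):
        male = make_pose()
        male.heading = np.array([0.0, 0.0])
        assert not bh.detect_orientation(male, make_pose(centroid=(100, 120)))


class TestTapping:
    def test_leg_on_torso_recognized(self, tapping_pairs):
        pair, gt = tapping_pairs["leg_on_torso"]
        assert gt.contact["male_leg_on_female_torso"]
        assert bh.detect_tapping(pair)

    def test_leg_under_wing_recognized(self, tapping_pairs):
        pair, gt = tapping_pairs["leg_under_wing"]
        assert gt.contact["male_leg_on_female_torso"]
        assert bh.detect_tapping(pair)

    def test_leg_on_wing_rejected(self, tapping_pairs):
        pair, gt = tapping_pairs["leg_on_wing"]
        assert not gt.contact["male_leg_on_female_torso"]
        assert not bh.detect_tapping(pair)

    def test_separated_bodies_fail_first_step(self, tapping_pairs):
        pair, _ = tapping_pairs["leg_on_torso"]
        # erase the leg bridge: bodies become two components
        from skimage.morphology import disk, opening

        stripped = bh.FramePair(
            male=pair.male, female=pair.female,
            body_mask=opening(pair.body_mask, disk(2)),
            torso_male=pair.torso_male, torso_female=pair.torso_female,
            wings_mask=pair.wings_mask, raw_crop=pair.raw_crop,
            mm_per_px=pair.mm_per_px)
        assert not bh.detect_tapping(stripped)

    def test_empty_masks_fail(self, tapping_pairs):
        pair, _ = tapping_pairs["leg_on_torso"]
        empty = np.zeros_like(pair.body_mask)
        stripped = bh.FramePair(
            male=pair.male, female=pair.female, body_mask=empty,
            torso_male=empty, torso_female=empty, wings_mask=empty,
            raw_crop=pair.raw_crop, mm_per_px=pair.mm_per_px)
        assert not bh.detect_tapping(stripped)


class TestAttemptedCopulation:
    def test_standard_value_is_09_of_reference(self):
        std = bh.EccentricityStandard(reference_eccentricity=0.95)
        assert std.standard_value == pytest.approx(0.855)

    def test_bent_male_near_tail(self):
        std = bh.EccentricityStandard(0.95)
        male = make_pose(centroid=(100, 100), eccentricity=0.80)
        # female tail 10 px (= 0.5 mm) from the male head at (100, 120)
        female = make_pose(centroid=(100, 150), heading_deg=0.0,
                           head_dist=20.0)
        assert bh.detect_attempted_copulation(male, female, std, MM_PER_PX)

    def test_straight_male_rejected(self):
        std = bh.EccentricityStandard(0.95)
        male = make_pose(eccentricity=0.90)  # above the 0.855 standard
        female = make_pose(centroid=(100, 150), heading_deg=0.0)
        assert not bh.detect_attempted_copulation(male, female, std, MM_PER_PX)

    def test_distance_gate(self):
        std = bh.EccentricityStandard(0.95)
        male = make_pose(eccentricity=0.80)
        far = make_pose(centroid=(100, 180), heading_deg=0.0)  # tail 2 mm away
        assert not bh.detect_attempted_copulation(male, far, std, MM_PER_PX)

    def test_missing_standard_raises(self):
        with pytest.raises(ValueError, match="standard"):
            bh.detect_attempted_copulation(make_pose(), make_pose(), None,
                                           MM_PER_PX)


class TestCalibration:
    def test_manual_frame(self):
        std = bh.calibrate_standard([0.8, 0.95, 0.9], mode="manual",
                                    manual_index=1)
        assert std.reference_eccentricity == pytest.approx(0.95)
        assert std.standard_value == pytest.approx(0.855)

    def test_auto_uses_upper_percentile_of_first_30s(self):
        rng = np.random.default_rng(0)
        straight = 0.95 + rng.normal(0, 0.004, 600)
        bent = np.full(120, 0.75)
        ecc = np.concatenate([straight[:300], bent, straight[300:]])
        std = bh.calibrate_standard(ecc, mode="auto", fps=24.0)
        assert std.reference_eccentricity == pytest.approx(0.95, abs=0.02)

    def test_all_bent_emits_warning(self):
        with pytest.warns(UserWarning, match="straight"):
            bh.calibrate_standard([0.6] * 100, mode="auto", fps=24.0)

    def test_no_valid_frames_raises(self):
        with pytest.raises(ValueError, match="no valid"):
            bh.calibrate_standard([], mode="auto")


class TestNoiseFilter:
    def test_six_of_twelve_certified(self):
        flags = [set()] * 6 + [{bh.SINGING}] * 6
        labels = bh.noise_filter(flags)
        assert labels[11] == bh.SINGING

    def test_five_of_twelve_not_certified(self):
        flags = ([set()] * 12 + [{bh.SINGING}] * 5 + [set()] * 12)
        labels = bh.noise_filter(flags)
        assert bh.SINGING not in labels

    def test_priority_collapse(self):
        assert bh.collapse_priority({bh.SINGING, bh.ORIENTATION}) == bh.SINGING
        assert bh.collapse_priority({bh.TAPPING, bh.SINGING}) == bh.TAPPING
        assert bh.collapse_priority(
            {bh.COPULATION, bh.ATTEMPTED, bh.TAPPING}) == bh.COPULATION
        assert bh.collapse_priority(set()) == bh.NONE

    def test_short_sequence_proportional_rule(self):
        # 4 hits in the first 6 frames: 4 > 5*6/12 -> certified early
        flags = [{bh.ORIENTATION}] * 4 + [set()] * 2
        labels = bh.noise_filter(flags)
        assert labels[3] == bh.ORIENTATION

    def test_long_gap_becomes_none(self):
        flags = [{bh.SINGING}] * 12 + [set()] * 20
        labels = bh.noise_filter(flags)
        assert labels[11] == bh.SINGING
        assert labels[-1] == bh.NONE

    def test_short_gap_inherits_previous_label(self):
        flags = ([{bh.SINGING}] * 12 + [set()] * 6 + [{bh.SINGING}] * 12)
        labels = bh.noise_filter(flags)
        assert all(lab == bh.SINGING for lab in labels[12:18])

    def test_every_frame_gets_exactly_one_label(self):
        rng = np.random.default_rng(5)
        pool = [bh.SINGING, bh.ORIENTATION, bh.TAPPING]
        flags = [set(rng.choice(pool, rng.integers(0, 3), replace=False))
                 for _ in range(200)]
        labels = bh.noise_filter(flags)
        valid = set(bh.PRIORITY) | {bh.NONE}
        assert len(labels) == 200
        assert all(lab in valid for lab in labels)

    def test_deterministic(self):
        flags = [{bh.SINGING} if i % 3 else set() for i in range(50)]
        assert bh.noise_filter(flags) == bh.noise_filter(flags)


class TestPromoteCopulation:
    def test_29_second_run_stays_attempted(self):
        labels = [bh.ATTEMPTED] * 696 + [bh.NONE] * 24  # 29 s at 24 fps
        out = bh.promote_copulation(labels, fps=24.0)
        assert bh.COPULATION not in out

    def test_exactly_30_seconds_not_promoted(self):
        labels = [bh.ATTEMPTED] * 720 + [bh.NONE] * 24  # boundary: not > 30 s
        out = bh.promote_copulation(labels, fps=24.0)
        assert bh.COPULATION not in out

    def test_31_second_run_promotes_rest_of_recording(self):
        labels = ([bh.SINGING] * 10 + [bh.ATTEMPTED] * 744 +
                  [bh.NONE] * 50 + [bh.SINGING] * 10)
        out = bh.promote_copulation(labels, fps=24.0)
        assert out[:10] == [bh.SINGING] * 10
        assert all(lab == bh.COPULATION for lab in out[10:])

    def test_no_attempted_copulation_unchanged(self):
        labels = [bh.SINGING, bh.NONE, bh.ORIENTATION] * 100
        assert bh.promote_copulation(labels, fps=24.0) == labels
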