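"""Background model, silhouette thresholding, wing/torso splitting."""

import numpy as np
import pytest

from flycourt.fixtures import FlySpec, SceneSpec
from flycourt.segmentation import (BinaryMask, build_background,
                                   extract_torso, extract_wings,
                                   subtract_and_threshold, wing_pixel_rule)
from flycourt.video_io import FrameImage

from conftest import gt_to_crop, render_and_segment


def _two_fly_scene(d_col=80.0):
    male = FlySpec(centroid=(120.0, 80.0), heading_angle=20.0,
                   torso_major=42, torso_minor=16)
    female = FlySpec(centroid=(120.0, 80.0 + d_col), heading_angle=200.0,
                     torso_major=56, torso_minor=24)
    return SceneSpec(flies=[male, female])


class TestBackground:
    def test_uniform_frame_unchanged(self):
        frame = FrameImage(np.full((50, 50, 3), 137, np.uint8), index=0)
        bg = build_background(frame, 11)
        assert np.array_equal(bg.pixels, frame.pixels)

    def test_matches_brute_force_window_maximum(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 255, (20, 20, 3)).astype(np.uint8)
        bg = build_background(FrameImage(px, index=0), 5).pixels
        # independent oracle: explicit loop over clipped windows, per channel
        for r, c in [(0, 0), (3, 17), (10, 10), (19, 2)]:
            win = px[max(0, r - 2):r + 3, max(0, c - 2):c + 3]
            assert np.array_equal(bg[r, c], win.reshape(-1, 3).max(axis=0))

    def test_large_window_erases_fly(self):
        crop, _, _ = render_and_segment(SceneSpec(flies=[
            FlySpec(centroid=(120, 120), heading_angle=0)]))
        bg = build_background(crop, 81)
        assert np.all(bg.pixels >= 185)  # everywhere close to backlight level

    def test_small_window_leaves_residual_blob(self):
        crop, _, _ = render_and_segment(SceneSpec(flies=[
            FlySpec(centroid=(120, 120), heading_angle=0, shape="ellipse")]))
        bg = build_background(crop, 9)  # smaller than the fly
        assert (bg.pixels.min(axis=2) < 100).sum() > 50

    @pytest.mark.parametrize("window", [2, 4, 1, -3])
    def test_invalid_window_rejected(self, window):
        frame = FrameImage(np.zeros((10, 10, 3), np.uint8), index=0)
        with pytest.raises(ValueError, match="odd"):
            build_background(frame, window)


class TestSilhouette:
    def test_frame_equal_to_background_gives_empty_mask(self):
        frame = FrameImage(np.full((40, 40, 3), 200, np.uint8), index=0)
        bg = build_background(frame, 11)
        assert subtract_and_threshold(frame, bg).area == 0

    def test_shape_mismatch_rejected(self):
        f1 = FrameImage(np.zeros((40, 40, 3), np.uint8), index=0)
        bg = build_background(FrameImage(np.zeros((30, 30, 3), np.uint8), 0), 11)
        with pytest.raises(ValueError, match="shape"):
            subtract_and_threshold(f1, bg)

    def test_two_separated_flies_two_components(self):
        crop, gt, masks = render_and_segment(_two_fly_scene(80.0))
        assert masks["body"].component_count() == 2
        from skimage.measure import label

        lab = label(masks["body"].pixels, connectivity=2)
        for i in range(2):
            gt_body = gt_to_crop(gt.body_masks[i])
            ids, counts = np.unique(lab[gt_body & (lab > 0)],
                                    return_counts=True)
            covered = (lab == ids[np.argmax(counts)])[gt_body].mean()
            assert covered >= 0.90

    def test_overlapping_flies_single_component(self):
        crop, gt, masks = render_and_segment(_two_fly_scene(30.0))
        assert gt.contact["bodies_touch"]
        assert masks["body"].component_count() == 1


class TestWingRule:
    @pytest.mark.parametrize("rgb,expected", [
        ((0, 0, 0), False),      # product 0
        ((80, 80, 80), True),    # product 1.0 -> round 1
        ((60, 60, 60), False),   # product 0.42 -> round 0
        ((64, 64, 64), True),    # product 0.512 -> round 1 (boundary)
    ])
    def test_channel_product_examples(self, rgb, expected):
        px = np.array([[rgb]], float)
        assert wing_pixel_rule(px)[0, 0] == expected

    def test_empty_body_gives_empty_wings(self):
        frame = FrameImage(np.full((30, 30, 3), 200, np.uint8), index=0)
        body = BinaryMask(np.zeros((30, 30), bool), "body")
        assert extract_wings(frame, body).area == 0

    def test_intensity_scaling_monotone(self):
        # more pixels pass the wing rule as global intensity grows
        grad = np.tile(np.linspace(0, 255, 256)[None, :, None], (4, 1, 3))
        counts = [wing_pixel_rule(np.clip(grad * s, 0, 255)).sum()
                  for s in (0.5, 0.75, 1.0, 1.5, 2.0)]
        assert counts == sorted(counts)


class TestTorsoExtraction:
    def test_wing_and_torso_masks_disjoint_within_body(self):
        scene = SceneSpec(flies=[FlySpec(centroid=(120, 110),
                                         heading_angle=40.0,
                                         left_wing_angle=60.0,
                                         right_wing_angle=25.0)])
        crop, gt, masks = render_and_segment(scene)
        torso, wings, body = (masks["torso"].pixels, masks["wings"].pixels,
                              masks["body"].pixels)
        assert not (torso & wings).any()
        assert ((torso | wings) & ~body).sum() == 0

    def test_torso_dice_against_ground_truth(self):
        scene = SceneSpec(flies=[FlySpec(centroid=(120, 110),
                                         heading_angle=70.0,
                                         left_wing_angle=45.0)])
        crop, gt, masks = render_and_segment(scene)
        gt_torso = gt_to_crop(gt.torso_masks[0])
        inter = (masks["torso"].pixels & gt_torso).sum()
        dice = 2 * inter / (masks["torso"].area + gt_torso.sum())
        assert dice >= 0.85

    def test_extended_wings_excluded_from_torso(self):
        scene = SceneSpec(flies=[FlySpec(centroid=(120, 110),
                                         heading_angle=10.0,
                                         left_wing_angle=90.0,
                                         right_wing_angle=90.0)])
        crop, gt, masks = render_and_segment(scene)
        gt_wings = gt_to_crop(gt.wing_masks[0])
        leaked = (masks["torso"].pixels & gt_wings).sum()
        assert leaked <= 0.05 * gt_wings.sum()

    def test_wings_empty_torso_equals_cleaned_body(self):
        scene = SceneSpec(flies=[FlySpec(centroid=(120, 120),
                                         heading_angle=0.0,
                                         wing_gray=30)])  # wings torso-dark
        crop, gt, masks = render_and_segment(scene)
        torso = extract_torso(masks["body"],
                              BinaryMask(np.zeros_like(masks["body"].pixels),
                                         "wings"))
        inter = (torso.pixels & masks["body"].pixels).sum()
        assert inter / masks["body"].area > 0.9
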