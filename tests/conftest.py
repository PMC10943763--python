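"""Shared fixtures: rendered scenes, segmented flies, and pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from flycourt.behavior import FramePair
from flycourt.config import PipelineConfig
from flycourt.fixtures import FlySpec, SceneSpec, render_frame, render_sequence
from flycourt.geometry import unit_vector
from flycourt.pipeline import run_pipeline
from flycourt.pose import measure_pose
from flycourt.scenarios import courtship_library, overlap_wander, tapping_scene
from flycourt.segmentation import build_background, segment_frame
from flycourt.video_io import ArenaRegion, crop_arena

ARENA = ArenaRegion(center=(120.0, 120.0), radius=110.0)
CROP_OFFSET = 10  # (center - radius) for the default 240x240 scene


@pytest.fixture(scope="session")
def arena():
    return ARENA


def render_and_segment(scene: SceneSpec, seed: int = 1):
    """Render a scene, crop the arena and run the segmentation stack."""
    frame, gt = render_frame(scene, seed=seed)
    crop = crop_arena(frame, ARENA)
    masks = segment_frame(crop, build_background(crop, 81))
    return crop, gt, masks


def gt_to_crop(mask: np.ndarray) -> np.ndarray:
    """Shift a full-frame ground-truth mask into arena-crop coordinates."""
    side = int(round(2 * ARENA.radius))
    return mask[CROP_OFFSET:CROP_OFFSET + side, CROP_OFFSET:CROP_OFFSET + side]


def single_fly_pose(scene: SceneSpec, seed: int = 1, previous_heading=None):
    crop, gt, masks = render_and_segment(scene, seed)
    pose = measure_pose(masks["torso"], masks["wings"], masks["body"],
                        previous_heading=previous_heading)
    return pose, gt, masks


def build_frame_pair(scene: SceneSpec, seed: int = 5,
                     male_prev_heading=None) -> tuple[FramePair, object]:
    """Two-fly scene -> FramePair with identities by torso size (male smaller)."""
    from skimage.measure import label as sklabel

    crop, gt, masks = render_and_segment(scene, seed)
    body, torso, wings = (masks["body"].pixels, masks["torso"].pixels,
                          masks["wings"].pixels)
    lab = sklabel(torso, connectivity=2)
    assert lab.max() == 2, f"expected 2 torso components, got {lab.max()}"
    areas = np.bincount(lab.ravel())
    areas[0] = 0
    order = np.argsort(areas)[::-1][:2]
    tm, tf = lab == order[1], lab == order[0]
    _, (ir, ic) = ndimage.distance_transform_edt(~(tm | tf), return_indices=True)
    owner_m = tm[ir, ic]
    pm = measure_pose(tm, wings & owner_m, body & owner_m,
                      previous_heading=male_prev_heading)
    pf = measure_pose(tf, wings & ~owner_m, body & ~owner_m)
    pair = FramePair(male=pm, female=pf, body_mask=body, torso_male=tm,
                     torso_female=tf, wings_mask=wings, raw_crop=crop,
                     mm_per_px=ARENA.mm_per_px, frame_index=0)
    return pair, gt


@pytest.fixture(scope="session")
def tapping_pairs():
    """FramePairs for the three leg-contact topologies."""
    out = {}
    prev = unit_vector(-25.0)  # the approach heading preceding contact
    for topo in ("leg_on_torso", "leg_under_wing", "leg_on_wing"):
        out[topo] = build_frame_pair(tapping_scene(topo),
                                     male_prev_heading=prev)
    return out


@pytest.fixture(scope="session")
def library_run():
    """Courtship scene library rendered and pushed through the pipeline."""
    lib = courtship_library()
    frames, gts = render_sequence(lib.scenes, seed=11, fps=lib.fps)
    result = run_pipeline(None, PipelineConfig(arena_count=1), frames=frames)[0]
    return lib, gts, result


@pytest.fixture(scope="session")
def wander_run():
    """500-frame two-fly wander with five full overlaps, tracked end to end."""
    script = overlap_wander(n_frames=500, n_overlaps=5)
    frames, gts = render_sequence(script.scenes, seed=13, fps=script.fps)
    result = run_pipeline(None, PipelineConfig(arena_count=1), frames=frames)[0]
    return script, result


def make_pose(centroid=(100.0, 100.0), heading_deg=0.0, head_dist=21.0,
              theta_l=0.0, theta_r=0.0, eccentricity=0.95,
              ambiguous=False, frame_index=0):
    """Hand-built FlyPose for detector geometry tests."""
    from flycourt.pose import FlyPose

    c = np.asarray(centroid, float)
    h = unit_vector(heading_deg)
    return FlyPose(
        torso_centroid=tuple(c), body_centroid=tuple(c - 2 * h),
        head=tuple(c + head_dist * h), tail=tuple(c - head_dist * h),
        heading=h, major_axis_px=2 * head_dist, minor_axis_px=16.0,
        eccentricity=eccentricity, left_wing_angle=theta_l,
        right_wing_angle=theta_r, frame_index=frame_index,
        orientation_defined=True, head_ambiguous=ambiguous)
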