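"""Scripted multi-frame scene builders with behavioral ground truth.

These compose :class:`~flycourt.fixtures.SceneSpec` sequences that exercise
specific parts of the pipeline: the three leg-contact topologies the
tapping cascade must distinguish, a courtship "scene library" covering all
five behavioral elements, and a long two-fly wander with repeated full
overlaps for identity tracking.

Expected labels for the courtship library account for the causal
certification filter: a new behavior needs six hits inside the 12-frame
window, so labels are expected to trail each scripted segment boundary by
five frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import COPULATION, NONE, ORIENTATION, SINGING, TAPPING
from .fixtures import FlySpec, SceneSpec
from .geometry import unit_vector

MALE_SIZE = (42.0, 16.0)
FEMALE_SIZE = (56.0, 24.0)
CERTIFICATION_LAG = 5  # frames a label trails a scripted segment boundary


def _male(centroid, heading, **kw) -> FlySpec:
    kw.setdefault("torso_major", MALE_SIZE[0])
    kw.setdefault("torso_minor", MALE_SIZE[1])
    return FlySpec(centroid=centroid, heading_angle=heading, **kw)


def _female(centroid, heading, **kw) -> FlySpec:
    kw.setdefault("torso_major", FEMALE_SIZE[0])
    kw.setdefault("torso_minor", FEMALE_SIZE[1])
    return FlySpec(centroid=centroid, heading_angle=heading, **kw)


# ---------------------------------------------------------------------------
# tapping topologies


def _local_coords(spec: FlySpec, point) -> tuple[float, float]:
    """Image (row, col) -> the fly's body-local (forward, left) frame."""
    v = np.asarray(point, float) - np.asarray(spec.centroid, float)
    f = float(np.dot(v, spec.heading_vec()))
    l = float(np.dot(v, spec.left_vec()))
    return f, l


def tapping_scene(topology: str = "leg_on_torso",
                  frame_size=(240, 240), gap_px: float | None = None) -> SceneSpec:
    """Two-fly scene realizing one leg-contact topology.

    ``leg_on_torso``: the male foreleg tip rests on the female abdomen with
    the torsos apart — tapping.  ``leg_under_wing``: the leg reaches the
    abdomen beneath the female's wing, which is swung back over the male —
    tapping.  ``leg_on_wing``: the leg touches only the female wing — not
    tapping.  The male's head stays within 1 mm of the female's tail in all
    three (step 3 of the cascade must pass so the later steps decide).
    """
    fem_c = np.array([112.0, 154.0])
    male_heading = -25.0     # approaching the female's rear from her right
    u = unit_vector(male_heading)
    if gap_px is None:
        gap_px = 4.0 if topology == "leg_under_wing" else 14.0

    fem = _female(tuple(fem_c), 0.0,
                  left_wing_angle=55.0, right_wing_angle=55.0)
    tail = np.array(fem.tail_point())
    male_c = tail - (gap_px + MALE_SIZE[0] / 2) * u
    male_head = tail - gap_px * u
    attach = (MALE_SIZE[0] / 2 - 4.0, 3.0)

    if topology == "leg_on_torso":
        # tip 8 px inside the abdomen, path over open background
        target = fem.to_image(-(FEMALE_SIZE[0] / 2 - 8.0), 2.0)
    elif topology == "leg_on_wing":
        # tip on the near wing blade, well short of the torso
        hinge = fem.wing_hinge()
        side = "right" if np.dot(male_c - fem_c, fem.left_vec()) < 0 else "left"
        tip = fem.wing_tip(side)
        target = hinge + 0.75 * (tip - hinge)
    elif topology == "leg_under_wing":
        # the near wing is swung back over the male's head so the leg path
        # to the abdomen runs beneath the blade; aim the blade a few px past
        # the head so its rounded end covers the head lobe
        tailward = -unit_vector(0.0)
        aim = male_head + 5.0 * u
        to_aim = aim - fem_c
        ang = float(np.rad2deg(np.arccos(
            np.clip(np.dot(tailward, to_aim) / np.linalg.norm(to_aim),
                    -1, 1))))
        on_left = np.dot(to_aim, fem.left_vec()) > 0
        wings = {"left_wing_angle": ang if on_left else 55.0,
                 "right_wing_angle": 55.0 if on_left else ang}
        fem = _female(tuple(fem_c), 0.0, **wings)
        target = fem.to_image(-(FEMALE_SIZE[0] / 2 - 8.0), 2.0)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    male_stub = _male(tuple(male_c), male_heading)
    legs = [(attach, _local_coords(male_stub, target))]
    male = _male(tuple(male_c), male_heading, leg_specs=legs)
    return SceneSpec(flies=[male, fem], frame_size=frame_size)


# ---------------------------------------------------------------------------
# courtship scene library


@dataclass
class LabeledScript:
    scenes: list
    intended: list       # scripted behavior per frame (ignores filter lag)
    expected: list       # intended with the certification lag applied
    fps: float


def _expected_from_intended(intended, fps: float,
                            lag: int = CERTIFICATION_LAG) -> list:
    out = []
    prev = NONE
    seg_start = 0
    for i, lab in enumerate(intended):
        if i > 0 and lab != intended[i - 1]:
            prev = out[-1]
            seg_start = i
        out.append(prev if i - seg_start < lag else lab)
    return out


def courtship_library(frame_size=(240, 240), fps: float = 1.0,
                      segment: int = 20) -> LabeledScript:
    """Scene sequence covering the five elements plus quiescence.

    Segments (each ``segment`` frames unless noted): none, orientation,
    singing, tapping, then 2x``segment`` frames of attempted copulation.
    At the script's timebase the attempted-copulation run exceeds half a
    minute, so the pipeline should promote it to copulation from its start.
    """
    scenes, intended = [], []
    fem_c = (120.0, 155.0)

    def female(heading: float = 0.0, **kw):
        return _female(fem_c, heading, **kw)

    # 1 -- far apart, male facing away; he turns toward her over the last
    # frames (headings change smoothly so temporal continuity holds)
    turn_frames = 6
    for i in range(segment):
        steps_left = segment - 1 - i
        heading = 180.0 if steps_left >= turn_frames else 30.0 * steps_left
        scenes.append(SceneSpec(
            flies=[_male((165.0, 70.0), heading), female()],
            frame_size=frame_size))
        intended.append(NONE)
    # 2 -- male faces the female inside the 2.5x sector radius (she stands
    # broadside so her centroid fits in the sector without body contact):
    # orientation
    for _ in range(segment):
        scenes.append(SceneSpec(
            flies=[_male((120.0, 111.0), 0.0), female(heading=90.0)],
            frame_size=frame_size))
        intended.append(ORIENTATION)
    # 3 -- same geometry, left wing extended: singing (outranks orientation)
    for _ in range(segment):
        scenes.append(SceneSpec(
            flies=[_male((120.0, 111.0), 0.0, left_wing_angle=55.0),
                   female(heading=90.0)],
            frame_size=frame_size))
        intended.append(SINGING)
    # 4 -- leg-on-abdomen contact: tapping
    tap = tapping_scene("leg_on_torso", frame_size)
    for _ in range(segment):
        scenes.append(tap)
        intended.append(TAPPING)
    # 5 -- bent abdomen at the female's tail: attempted copulation, long
    # enough (> 30 s at this timebase) to be promoted to copulation
    fem = female()
    tail = np.array(fem.tail_point())
    u = unit_vector(0.0)
    male_c = tail - (10.0 + MALE_SIZE[0] / 2) * u
    for _ in range(2 * segment):
        scenes.append(SceneSpec(
            flies=[_male(tuple(male_c), 0.0, abdomen_bend=130.0), fem],
            frame_size=frame_size))
        intended.append(COPULATION)
    expected = _expected_from_intended(intended, fps)
    return LabeledScript(scenes=scenes, intended=intended,
                         expected=expected, fps=fps)


# ---------------------------------------------------------------------------
# identity wander with full overlaps


def overlap_wander(n_frames: int = 500, n_overlaps: int = 5,
                   frame_size=(240, 240), seed: int = 7) -> LabeledScript:
    """Two flies on smooth orbits that fully coincide ``n_overlaps`` times.

    The male (smaller) circles the arena; the female drifts on a slower
    counter-orbit.  At evenly spaced episodes the male's path is warped to
    pass through the female's position, producing approach, full overlap
    (a few frames), and separation.  Ground truth is the scripted centroid
    of each fly per frame.
    """
    rng = np.random.default_rng(seed)
    center = np.array([120.0, 120.0])
    scenes = []
    truth = []
    episode_frames = set()
    episodes = np.linspace(0.12, 0.88, n_overlaps) * n_frames
    for e in episodes:
        for k in range(-2, 3):
            episode_frames.add(int(e) + k)
    for t in range(n_frames):
        a1 = 2 * np.pi * t / 240.0
        a2 = -2 * np.pi * t / 400.0 + 1.7
        male_c = center + 58 * np.array([np.sin(a1), np.cos(a1)])
        fem_c = center + 40 * np.array([np.sin(a2), np.cos(a2)])
        # warp the male onto the female around overlap episodes
        d = min((abs(t - e) for e in episodes), default=np.inf)
        if d <= 6:
            w = max(0.0, 1.0 - d / 6.0)
            male_c = (1 - w) * male_c + w * fem_c
        mh = np.rad2deg(a1) % 360.0
        fh = np.rad2deg(-a2) % 360.0
        male = _male(tuple(male_c), mh)
        fem = _female(tuple(fem_c), fh)
        scenes.append(SceneSpec(flies=[male, fem], frame_size=frame_size))
        truth.append({"male": tuple(male_c), "female": tuple(fem_c),
                      "overlap": bool(np.hypot(*(male_c - fem_c)) < 25)})
    _ = rng
    return LabeledScript(scenes=scenes, intended=truth, expected=truth,
                         fps=24.0)
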