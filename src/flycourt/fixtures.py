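"""Parametric synthetic two-fly arena scenes with exact ground truth.

The renderer emulates the backlit imaging geometry of a courtship rig: a
bright circular arena on a dark surround, flies drawn as dark torsos with
translucent (intermediate-gray) wings and 1-px legs.  Channels are
near-equal (R=G=B up to independent pixel noise) so the channel-product
wing rule is exercised nontrivially.

Every frame comes with a :class:`GroundTruth` carrying per-fly masks,
poses and contact flags, so each downstream stage of the pipeline can be
validated without recorded video.

Geometry of a fly (all lengths in px, angles in degrees, see
:mod:`flycourt.geometry` for the coordinate convention):

* torso: either a single filled ellipse (``shape="ellipse"``) or three
  overlapping lobes — head, thorax, abdomen — along the body axis
  (``shape="lobed"``), the latter giving the distance-transform basin
  structure a real fly torso has;
* wings: kite-shaped polygons hinged at the posterior quarter of the
  torso, tip at 1.2 x the torso semi-major axis from the torso centroid,
  at the requested extension angle from the tailward axis direction;
* legs: 1-px line segments specified in body-local (forward, left)
  coordinates; a leg pixel under a wing is darkened multiplicatively
  (translucent wing over a leg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .geometry import rotate_about, unit_vector
from .video_io import FrameImage

ARENA_DIAMETER_MM = 11.0

# Lobe layout of the three-part torso, as fractions of the torso semi-axes.
# Chosen so the distance map of the rendered torso has three basins whose
# necks are clearly shallower than the lobe peaks.
_LOBE_HEAD_R = 0.60        # head radius / semi-minor
_LOBE_THORAX_A = 0.41      # thorax semi-major / torso semi-major
_LOBE_THORAX_B = 0.80      # thorax semi-minor / torso semi-minor
_LOBE_THORAX_F = 0.145     # thorax center offset / torso semi-major


@dataclass
class FlySpec:
    """Parametric description of one fly.

    ``leg_specs`` are ((f0, l0), (f1, l1)) segments in body-local
    coordinates: ``f`` along the heading from the torso centroid, ``l``
    to the fly's left.
    """

    centroid: tuple[float, float]
    heading_angle: float
    torso_major: float = 44.0
    torso_minor: float = 18.0
    left_wing_angle: float = 0.0
    right_wing_angle: float = 0.0
    leg_specs: Sequence[tuple[tuple[float, float], tuple[float, float]]] = ()
    abdomen_bend: float = 0.0
    body_gray: int = 30
    wing_gray: int = 140
    leg_gray: int = 110
    shape: str = "lobed"

    def __post_init__(self) -> None:
        if not (self.torso_major >= self.torso_minor > 0):
            raise ValueError("torso_major >= torso_minor > 0 required")
        for w in (self.left_wing_angle, self.right_wing_angle):
            if not (0 <= w < 180):
                raise ValueError("wing angles must lie in [0, 180)")
        if self.shape not in ("ellipse", "lobed"):
            raise ValueError(f"unknown torso shape {self.shape!r}")

    # -- derived geometry ------------------------------------------------
    @property
    def semi_major(self) -> float:
        return self.torso_major / 2.0

    @property
    def semi_minor(self) -> float:
        return self.torso_minor / 2.0

    def heading_vec(self) -> np.ndarray:
        return unit_vector(self.heading_angle)

    def left_vec(self) -> np.ndarray:
        return unit_vector(self.heading_angle + 90.0)

    def to_image(self, f: float, l: float) -> np.ndarray:
        """Body-local (forward, left) -> image (row, col)."""
        c = np.asarray(self.centroid, float)
        return c + f * self.heading_vec() + l * self.left_vec()

    def head_point(self) -> np.ndarray:
        return self.to_image(self.semi_major, 0.0)

    def tail_point(self) -> np.ndarray:
        return self.to_image(-self.semi_major, 0.0)

    def wing_hinge(self) -> np.ndarray:
        return self.to_image(-self.semi_major / 2.0, 0.0)

    def torso_moment_centroid(self) -> np.ndarray:
        """Centroid of the rendered torso mask (the lobed torso is
        abdomen-heavy, so this sits tailward of the geometric centroid)."""
        pad = int(np.ceil(self.torso_major)) + 4
        local = FlySpec(centroid=(float(pad), float(pad)),
                        heading_angle=self.heading_angle,
                        torso_major=self.torso_major,
                        torso_minor=self.torso_minor,
                        abdomen_bend=self.abdomen_bend, shape=self.shape)
        mask = _draw_torso(local, (2 * pad, 2 * pad))
        ys, xs = np.nonzero(mask)
        off = np.array([ys.mean() - pad, xs.mean() - pad])
        return np.asarray(self.centroid, float) + off

    def wing_tip(self, side: str) -> np.ndarray:
        """Wing tip, at 1.2 x the torso semi-major axis from the torso
        (moment) centroid so measured extension angles match the spec."""
        angle = self.left_wing_angle if side == "left" else self.right_wing_angle
        sign = 1.0 if side == "left" else -1.0
        direction = unit_vector(self.heading_angle + 180.0 - sign * angle)
        return self.torso_moment_centroid() + 1.2 * self.semi_major * direction

    def ellipse_eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.torso_minor / self.torso_major) ** 2))


@dataclass
class SceneSpec:
    """One arena, one frame: background, arena circle and the flies (male first)."""

    flies: list[FlySpec] = field(default_factory=list)
    frame_size: tuple[int, int] = (240, 240)
    arena_center: tuple[float, float] | None = None
    arena_radius: float = 110.0
    background_gray: int = 200
    outside_gray: int = 60
    noise_sd: float = 2.0
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.arena_center is None:
            self.arena_center = (self.frame_size[0] / 2.0, self.frame_size[1] / 2.0)
        if self.mm_per_px is None:
            self.mm_per_px = ARENA_DIAMETER_MM / (2.0 * self.arena_radius)
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        for fly in self.flies:
            d = np.hypot(fly.centroid[0] - self.arena_center[0],
                         fly.centroid[1] - self.arena_center[1])
            if d >= self.arena_radius:
                raise ValueError(
                    f"fly centroid {fly.centroid} outside arena "
                    f"(center {self.arena_center}, radius {self.arena_radius})")


@dataclass
class GroundTruth:
    """Exact per-frame ground truth for a rendered scene."""

    torso_masks: list[np.ndarray]
    wing_masks: list[np.ndarray]
    leg_masks: list[np.ndarray]
    body_masks: list[np.ndarray]
    poses: list[dict]
    contact: dict
    arena_center: tuple[float, float]
    arena_radius: float
    mm_per_px: float

    def to_json_dict(self) -> dict:
        """Lossy JSON form (poses and flags; masks as run-length counts)."""
        return {
            "poses": self.poses,
            "contact": self.contact,
            "arena_center": list(self.arena_center),
            "arena_radius": self.arena_radius,
            "mm_per_px": self.mm_per_px,
            "mask_areas": {
                "torso": [int(m.sum()) for m in self.torso_masks],
                "wings": [int(m.sum()) for m in self.wing_masks],
                "legs": [int(m.sum()) for m in self.leg_masks],
            },
        }


# ---------------------------------------------------------------------------
# rasterization helpers


def _draw_torso(spec: FlySpec, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, bool)
    a, b = spec.semi_major, spec.semi_minor
    c = np.asarray(spec.centroid, float)
    ang = spec.heading_angle
    bend = spec.abdomen_bend

    def fill_ellipse(center, ra, rb, axis_angle):
        rr, cc = draw_ellipse(center[0], center[1], rb, ra,
                              shape=shape, rotation=np.deg2rad(axis_angle))
        mask[rr, cc] = True

    def fill_disk(center, r):
        rr, cc = draw_disk((center[0], center[1]), r, shape=shape)
        mask[rr, cc] = True

    if spec.shape == "ellipse":
        if bend == 0:
            fill_ellipse(c, a, b, ang)
        else:
            # two overlapping half-ellipses, rear one rotated by the bend
            fill_ellipse(spec.to_image(0.3 * a, 0.0), 0.7 * a, b, ang)
            rear_dir = unit_vector(ang + 180.0 + bend)
            fill_ellipse(c + 0.3 * a * rear_dir, 0.7 * a, b, ang + bend)
        return mask

    # lobed torso: abdomen disk, thorax ellipse, head disk
    r_head = _LOBE_HEAD_R * b
    r_abd = b
    f_head = a - r_head
    f_abd = -(a - r_abd)
    abd_center = spec.to_image(f_abd, 0.0)
    if bend != 0:
        pivot = spec.to_image(f_abd + r_abd, 0.0)
        abd_center = rotate_about(abd_center, pivot, bend)
    fill_disk(abd_center, r_abd)
    fill_ellipse(spec.to_image(_LOBE_THORAX_F * a, 0.0),
                 _LOBE_THORAX_A * a, _LOBE_THORAX_B * b, ang)
    fill_disk(spec.to_image(f_head, 0.0), r_head)
    return mask


def _draw_wings(spec: FlySpec, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, bool)
    hinge = spec.wing_hinge()
    for side in ("left", "right"):
        angle = spec.left_wing_angle if side == "left" else spec.right_wing_angle
        tip = spec.wing_tip(side)
        v = tip - hinge
        length = np.linalg.norm(v)
        if length == 0:
            continue
        perp = np.array([-v[1], v[0]]) / length
        mid = hinge + 0.6 * v
        w = 0.22 * length
        pts = np.array([hinge, mid + w * perp, tip, mid - w * perp])
        rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=shape)
        mask[rr, cc] = True
        # rounded (paddle-like) tip: a real wing blade does not taper to a
        # point; centering the cap on the tip keeps the farthest boundary
        # point on the centroid-to-tip ray, so measured extension angles
        # stay exact
        r_tip = 0.45 * w
        if r_tip >= 1.0:
            rr, cc = draw_disk(tip, r_tip, shape=shape)
            mask[rr, cc] = True
        # degenerate-thin wings still leave a trace
        rr, cc = draw_line(int(round(hinge[0])), int(round(hinge[1])),
                           int(round(tip[0])), int(round(tip[1])))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
        _ = angle
    return mask


def _draw_legs(spec: FlySpec, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, bool)
    for (f0, l0), (f1, l1) in spec.leg_specs:
        p0 = spec.to_image(f0, l0)
        p1 = spec.to_image(f1, l1)
        rr, cc = draw_line(int(round(p0[0])), int(round(p0[1])),
                           int(round(p1[0])), int(round(p1[1])))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    return mask


def default_legs(spread: float = 1.0) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Six legs attached near the thorax, tips splayed outward.

    Coordinates are fractions of nothing in particular — they are scaled by
    the caller through body-local px values; this helper returns px offsets
    sized for the default torso (44 x 18 px).
    """
    legs = []
    for f_att, f_tip, l_tip in ((8, 20, 14), (2, 4, 18), (-4, -14, 16)):
        for side in (1.0, -1.0):
            legs.append(((f_att, side * 6.0), (f_tip, side * l_tip * spread)))
    return legs


def _masks_touch(a: np.ndarray, b: np.ndarray) -> bool:
    """8-connectivity touch or overlap between two boolean masks."""
    if not a.any() or not b.any():
        return False
    if (a & b).any():
        return True
    from scipy.ndimage import binary_dilation
    return bool((binary_dilation(a, np.ones((3, 3), bool)) & b).any())


def _leg_touches(leg_mask: np.ndarray, target: np.ndarray) -> bool:
    return _masks_touch(leg_mask, target)


# ---------------------------------------------------------------------------
# public API


def render_frame(scene: SceneSpec, seed: int, index: int = 0,
                 fps: float = 24.0) -> tuple[FrameImage, GroundTruth]:
    """Render one frame and its exact ground truth.

    Deterministic: identical scene + seed give bit-identical pixels.
    """
    shape = tuple(scene.frame_size)
    canvas = np.full(shape, float(scene.outside_gray))
    rr, cc = draw_disk(scene.arena_center, scene.arena_radius, shape=shape)
    canvas[rr, cc] = scene.background_gray

    n = len(scene.flies)
    raw_torso = [_draw_torso(f, shape) for f in scene.flies]
    raw_wings = [_draw_wings(f, shape) for f in scene.flies]
    raw_legs = [_draw_legs(f, shape) for f in scene.flies]

    all_wings = np.zeros(shape, bool)
    for i, f in enumerate(scene.flies):
        canvas[raw_wings[i]] = f.wing_gray
        all_wings |= raw_wings[i]
    for i, f in enumerate(scene.flies):
        under = raw_legs[i] & all_wings
        bare = raw_legs[i] & ~all_wings
        canvas[bare] = f.leg_gray
        # translucent wing over a leg: multiplicative darkening
        for j, g in enumerate(scene.flies):
            dark = np.round(f.leg_gray * g.wing_gray / 255.0)
            canvas[under & raw_wings[j]] = dark
    all_torso = np.zeros(shape, bool)
    for i, f in enumerate(scene.flies):
        canvas[raw_torso[i]] = f.body_gray
        all_torso |= raw_torso[i]

    # occlusion-resolved ground-truth masks (later flies drawn on top)
    torso_masks, wing_masks, leg_masks, body_masks = [], [], [], []
    for i in range(n):
        above = np.zeros(shape, bool)
        for j in range(i + 1, n):
            above |= raw_torso[j]
        t = raw_torso[i] & ~above
        w = raw_wings[i] & ~all_torso
        l = raw_legs[i] & ~all_torso & ~w
        torso_masks.append(t)
        wing_masks.append(w)
        leg_masks.append(l)
        body_masks.append(t | w | l)

    poses = []
    for i, f in enumerate(scene.flies):
        poses.append({
            "centroid": [float(f.centroid[0]), float(f.centroid[1])],
            "heading_angle": float(f.heading_angle % 360.0),
            "head": [float(v) for v in f.head_point()],
            "tail": [float(v) for v in f.tail_point()],
            "left_wing_angle": float(f.left_wing_angle),
            "right_wing_angle": float(f.right_wing_angle),
            "major_axis_px": float(f.torso_major),
            "minor_axis_px": float(f.torso_minor),
            "eccentricity": _mask_eccentricity(raw_torso[i])
            if (f.shape == "lobed" or f.abdomen_bend != 0)
            else f.ellipse_eccentricity(),
            "abdomen_bend": float(f.abdomen_bend),
        })

    contact = _contact_flags(scene, torso_masks, wing_masks, leg_masks,
                             body_masks, raw_legs)

    rng = np.random.default_rng(seed)
    rgb = canvas[..., None] + rng.normal(0.0, scene.noise_sd, shape + (3,))
    pixels = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    frame = FrameImage(pixels=pixels, index=index, fps=fps)
    gt = GroundTruth(torso_masks=torso_masks, wing_masks=wing_masks,
                     leg_masks=leg_masks, body_masks=body_masks, poses=poses,
                     contact=contact, arena_center=tuple(scene.arena_center),
                     arena_radius=scene.arena_radius, mm_per_px=scene.mm_per_px)
    return frame, gt


def _mask_eccentricity(mask: np.ndarray) -> float:
    ys, xs = np.nonzero(mask)
    if len(ys) < 3:
        return 0.0
    cov = np.cov(np.vstack([ys, xs]))
    w = np.linalg.eigvalsh(cov)
    if w[1] <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - w[0] / w[1])))


def _contact_flags(scene, torso_masks, wing_masks, leg_masks, body_masks,
                   raw_legs) -> dict:
    n = len(scene.flies)
    contact = {
        "bodies_touch": False,
        "torsos_touch": False,
        "coincident": False,
        "male_leg_on_female_torso": False,
        "male_leg_on_female_wing": False,
    }
    if n >= 2:
        contact["bodies_touch"] = _masks_touch(body_masks[0], body_masks[1])
        contact["torsos_touch"] = _masks_touch(torso_masks[0], torso_masks[1])
        c0 = np.asarray(scene.flies[0].centroid)
        c1 = np.asarray(scene.flies[1].centroid)
        contact["coincident"] = bool(np.hypot(*(c0 - c1)) < 2.0)
        # use un-occluded leg pixels: a leg tip under the female torso still taps
        contact["male_leg_on_female_torso"] = _leg_touches(raw_legs[0], torso_masks[1])
        contact["male_leg_on_female_wing"] = _leg_touches(
            raw_legs[0] & ~torso_masks[1], wing_masks[1])
    return contact


def render_sequence(scenes: Sequence[SceneSpec], seed: int,
                    fps: float = 24.0) -> tuple[list[FrameImage], list[GroundTruth]]:
    """Render a scripted sequence of scenes deterministically.

    Each frame gets an independent noise stream spawned from ``seed``; the
    same scene list and seed give bit-identical frames.
    """
    if len(scenes) == 0:
        raise ValueError("empty scene list")
    size = scenes[0].frame_size
    for s in scenes:
        if tuple(s.frame_size) != tuple(size):
            raise ValueError("inconsistent frame sizes in sequence")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(scenes))
    frames, gts = [], []
    for i, (s, cs) in enumerate(zip(scenes, child_seeds)):
        fr, gt = render_frame(s, int(cs) % (2 ** 31), index=i, fps=fps)
        frames.append(fr)
        gts.append(gt)
    return frames, gts


def write_png_sequence(frames: Sequence[FrameImage], directory) -> list[Path]:
    """Write frames as a zero-padded PNG sequence; returns the paths."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for fr in frames:
        p = directory / f"frame_{fr.index:05d}.png"
        iio.imwrite(p, fr.pixels)
        paths.append(p)
    return paths


def write_ground_truth_json(gts: Sequence[GroundTruth], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([g.to_json_dict() for g in gts], indent=1))
    return path
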