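"""Per-fly geometric characterization from torso and wing masks.

The torso's moment-equivalent ellipse gives the fly's position (torso
centroid), its major axis (head/tail candidates at the axis endpoints) and
its eccentricity sqrt(1 - (minor/major)^2).  The head is the axis endpoint
farther from the whole-body centroid: the wings trail behind the fly and
pull the body centroid tailward.  Wing extension angles theta (left) and
theta' (right) are measured between the tailward major-axis direction and
the vector from the torso centroid to each side's wingtip, so folded wings
read ~0 deg and right-angle extension reads ~90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops
from skimage.morphology import erosion

from .geometry import angle_between, unit_vector
from .segmentation import BinaryMask


@dataclass
class FlyPose:
    torso_centroid: tuple[float, float]
    body_centroid: tuple[float, float]
    head: tuple[float, float]
    tail: tuple[float, float]
    heading: np.ndarray  # unit (row, col) vector
    major_axis_px: float
    minor_axis_px: float
    eccentricity: float
    left_wing_angle: float = 0.0
    right_wing_angle: float = 0.0
    left_wing_tip: tuple[float, float] | None = None
    right_wing_tip: tuple[float, float] | None = None
    frame_index: int = 0
    orientation_defined: bool = True
    head_ambiguous: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def heading_angle(self) -> float:
        return float(np.rad2deg(np.arctan2(-self.heading[0], self.heading[1])) % 360.0)


class PoseError(ValueError):
    pass


def fit_torso(torso: BinaryMask | np.ndarray) -> dict:
    """Moment-ellipse fit of a single-component torso mask.

    Returns centroid, full axis lengths, the two major-axis endpoints
    (head/tail candidates) and the eccentricity.  A near-circular torso
    (axis ratio ~1) has no usable orientation and is flagged.
    """
    mask = torso.pixels if isinstance(torso, BinaryMask) else np.asarray(torso, bool)
    if not mask.any():
        raise PoseError("empty torso mask")
    lab = label(mask, connectivity=2)
    if lab.max() != 1:
        raise PoseError(f"torso mask has {lab.max()} components, expected 1")
    if mask.sum() < 20:
        raise PoseError("torso mask smaller than 20 px")
    props = regionprops(lab.astype(np.uint8))[0]
    centroid = tuple(float(v) for v in props.centroid)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    ecc = float(props.eccentricity)
    orientation_defined = major > 0 and (minor / major) < 0.98
    # skimage orientation is measured from the row axis; convert to the
    # package convention (degrees CCW from +col): axis angle = o + 90 deg.
    axis_angle = float(np.rad2deg(props.orientation)) + 90.0
    axis_dir = unit_vector(axis_angle)
    c = np.array(centroid)
    cand_a = c + (major / 2.0) * axis_dir
    cand_b = c - (major / 2.0) * axis_dir
    return {
        "centroid": centroid,
        "major_axis_px": major,
        "minor_axis_px": minor,
        "eccentricity": ecc,
        "axis_angle_deg": axis_angle % 180.0,
        "candidates": (tuple(cand_a), tuple(cand_b)),
        "orientation_defined": orientation_defined,
        "area": int(mask.sum()),
    }


def assign_head_tail(candidates, torso_centroid, body_centroid,
                     previous_heading=None, tie_px: float = 0.5):
    """Pick the head as the axis endpoint farther from the body centroid.

    When the two distances agree within ``tie_px`` the geometry is
    ambiguous (symmetric body, folded wings); the previous frame's heading
    breaks the tie and the ambiguity is flagged.
    """
    a, b = (np.array(candidates[0], float), np.array(candidates[1], float))
    bc = np.array(body_centroid, float)
    tc = np.array(torso_centroid, float)
    da, db = np.linalg.norm(a - bc), np.linalg.norm(b - bc)
    ambiguous = abs(da - db) < tie_px
    if ambiguous and previous_heading is not None:
        head = a if np.dot(a - tc, previous_heading) >= np.dot(b - tc, previous_heading) else b
        tail = b if head is a else a
        return tuple(head), tuple(tail), True
    head, tail = (a, b) if da >= db else (b, a)
    if previous_heading is not None and np.linalg.norm(previous_heading) > 0:
        # a near-180 heading flip with only weak body-centroid evidence
        # means the centroid was contaminated (e.g. the other fly's wing
        # overlapping this fly); temporal continuity wins then, but a
        # decisive centroid offset is trusted so a genuine fast turn is
        # not overridden
        margin = abs(da - db)
        weak = margin < 0.15 * np.linalg.norm(a - b)
        hv = head - tc
        nh = np.linalg.norm(hv)
        if weak and nh > 0:
            cosang = np.dot(hv / nh, np.asarray(previous_heading, float))
            if cosang < -0.5:
                head, tail = tail, head
                ambiguous = True
    return tuple(head), tuple(tail), ambiguous


def wing_angles(wings: BinaryMask | np.ndarray, torso_centroid, heading) -> dict:
    """Wing extension angles from the wing-mask boundary.

    Boundary pixels are split into left/right by the sign of the cross
    product of the heading with each pixel's wing vector; per side the
    farthest boundary pixel from the torso centroid is the wingtip, and the
    angle is measured against the tailward axis direction.  An empty wing
    mask gives 0 deg on both sides.
    """
    mask = wings.pixels if isinstance(wings, BinaryMask) else np.asarray(wings, bool)
    out = {"left": 0.0, "right": 0.0, "left_tip": None, "right_tip": None}
    if not mask.any():
        return out
    edge = mask & ~erosion(mask, np.ones((3, 3), bool))
    ys, xs = np.nonzero(edge if edge.any() else mask)
    c = np.array(torso_centroid, float)
    h = np.asarray(heading, float)
    tailward = -h
    vecs = np.stack([ys - c[0], xs - c[1]], axis=1)
    crosses = h[0] * vecs[:, 1] - h[1] * vecs[:, 0]
    dists = np.hypot(vecs[:, 0], vecs[:, 1])
    for side, sel in (("left", crosses > 0), ("right", crosses < 0)):
        if not sel.any():
            continue
        i = np.argmax(np.where(sel, dists, -1.0))
        tip = (float(ys[i]), float(xs[i]))
        out[side] = angle_between(tailward, vecs[i])
        out[f"{side}_tip"] = tip
    return out


def measure_pose(torso: BinaryMask | np.ndarray, wings: BinaryMask | np.ndarray,
                 body: BinaryMask | np.ndarray | None = None,
                 previous_heading=None, frame_index: int = 0) -> FlyPose:
    """Full pose for one fly from its torso/wing (and optional body) masks."""
    fit = fit_torso(torso)
    tmask = torso.pixels if isinstance(torso, BinaryMask) else np.asarray(torso, bool)
    wmask = wings.pixels if isinstance(wings, BinaryMask) else np.asarray(wings, bool)
    if body is not None:
        bmask = body.pixels if isinstance(body, BinaryMask) else np.asarray(body, bool)
    else:
        bmask = tmask | wmask
    ys, xs = np.nonzero(bmask)
    body_centroid = (float(ys.mean()), float(xs.mean()))
    head, tail, ambiguous = assign_head_tail(
        fit["candidates"], fit["centroid"], body_centroid, previous_heading)
    hv = np.array(head) - np.array(fit["centroid"])
    n = np.linalg.norm(hv)
    heading = hv / n if n > 0 else np.array([0.0, 1.0])
    wa = wing_angles(wmask, fit["centroid"], heading)
    return FlyPose(
        torso_centroid=fit["centroid"], body_centroid=body_centroid,
        head=head, tail=tail, heading=heading,
        major_axis_px=fit["major_axis_px"], minor_axis_px=fit["minor_axis_px"],
        eccentricity=fit["eccentricity"],
        left_wing_angle=wa["left"], right_wing_angle=wa["right"],
        left_wing_tip=wa["left_tip"], right_wing_tip=wa["right_tip"],
        frame_index=frame_index,
        orientation_defined=fit["orientation_defined"],
        head_ambiguous=ambiguous,
    )


def pose_row(pose: FlyPose, fly_id: str) -> dict:
    """Flatten a pose to the per-frame CSV row schema."""
    return {
        "frame": pose.frame_index,
        "fly_id": fly_id,
        "row": pose.torso_centroid[0],
        "col": pose.torso_centroid[1],
        "heading_deg": pose.heading_angle,
        "theta_L": pose.left_wing_angle,
        "theta_R": pose.right_wing_angle,
        "eccentricity": pose.eccentricity,
        "head_row": pose.head[0],
        "head_col": pose.head[1],
        "tail_row": pose.tail[0],
        "tail_col": pose.tail[1],
    }
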