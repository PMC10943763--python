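"""Per-frame classification of the male's courtship behavior.

Five behavioral elements are recognized from poses and masks:

* singing — a wing extension angle above 30 deg;
* orientation — the female torso centroid inside a sector along the male
  heading (radius 2.5 x the centroid-to-head distance, half-angle 10 deg);
* tapping — a foreleg of the male touching the female's torso, decided by
  a six-step cascade on silhouette/torso/skeleton connectivity;
* attempted copulation — male torso eccentricity below 0.9 x a straight
  reference with his head within 1 mm of the female's tail;
* copulation — attempted copulation sustained for over half a minute, and
  everything after its onset.

Raw per-frame flags are collapsed by priority (copulation > attempted
copulation > tapping > singing > orientation), certified by a more-than-5-
of-12-frame temporal filter, and gaps shorter than 12 frames inherit the
previous certified label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.measure import label as sklabel
from skimage.morphology import disk, erosion, remove_small_objects

from .geometry import angle_between
from .pose import FlyPose
from .video_io import FrameImage

NONE = "none"
ORIENTATION = "orientation"
TAPPING = "tapping"
SINGING = "singing"
ATTEMPTED = "attempted_copulation"
COPULATION = "copulation"

# highest first
PRIORITY = (COPULATION, ATTEMPTED, TAPPING, SINGING, ORIENTATION)
COURTSHIP_ELEMENTS = (ORIENTATION, TAPPING, SINGING, ATTEMPTED)


@dataclass
class BehaviorParams:
    singing_deg: float = 30.0
    orient_ext: float = 2.5
    orient_halfangle: float = 10.0
    contact_mm: float = 1.0
    ecc_factor: float = 0.9
    cop_seconds: float = 30.0
    filter_window: int = 12
    filter_min_hits: int = 5      # certified when hits exceed this
    none_gap: int = 12
    skel_branch_px: int = 5
    erode_radius: int = 2
    denoise_px: int = 10


@dataclass
class EccentricityStandard:
    """Reference eccentricity of a straight (unbent) male torso."""

    reference_eccentricity: float
    factor: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.reference_eccentricity < 1):
            raise ValueError("reference eccentricity must lie in (0, 1)")

    @property
    def standard_value(self) -> float:
        return self.factor * self.reference_eccentricity


@dataclass
class FramePair:
    """Everything the behavior detectors need for one frame of one arena."""

    male: FlyPose
    female: FlyPose
    body_mask: np.ndarray          # combined silhouette (both flies)
    torso_male: np.ndarray
    torso_female: np.ndarray
    wings_mask: np.ndarray         # combined wing mask
    raw_crop: FrameImage | None
    mm_per_px: float
    frame_index: int = 0


@dataclass
class BehaviorRecord:
    frame_index: int
    raw_flags: set = field(default_factory=set)
    label: str = NONE


# ---------------------------------------------------------------------------
# element detectors


def detect_singing(male: FlyPose, threshold_deg: float = 30.0) -> bool:
    """Singing: either wing extended strictly beyond the threshold."""
    return max(male.left_wing_angle, male.right_wing_angle) > threshold_deg


def detect_orientation(male: FlyPose, female: FlyPose,
                       extension: float = 2.5,
                       half_angle_deg: float = 10.0) -> bool:
    """Orientation: female torso centroid inside the male's view sector.

    The sector apex is the male torso centroid, its axis the heading, its
    radius ``extension`` times the centroid-to-head distance and its
    half-angle ``half_angle_deg``.
    """
    h = np.asarray(male.heading, float)
    if np.linalg.norm(h) == 0 or not male.orientation_defined:
        return False
    apex = np.asarray(male.torso_centroid, float)
    target = np.asarray(female.torso_centroid, float) - apex
    radius = extension * np.linalg.norm(
        np.asarray(male.head, float) - apex)
    dist = np.linalg.norm(target)
    if dist > radius or dist == 0:
        return False
    return angle_between(h, target) <= half_angle_deg


def _head_tail_distance_mm(male: FlyPose, female: FlyPose, mm_per_px: float) -> float:
    d = np.linalg.norm(np.asarray(male.head) - np.asarray(female.tail))
    if female.head_ambiguous:
        d = min(d, np.linalg.norm(np.asarray(male.head) - np.asarray(female.head)))
    return float(d * mm_per_px)


def _components(mask: np.ndarray) -> np.ndarray:
    return sklabel(mask, connectivity=2)


def _connected(mask: np.ndarray, a: np.ndarray, b: np.ndarray) -> bool:
    """True when regions a and b fall in one 8-connected component of mask."""
    lab = _components(mask)
    ids_a = set(np.unique(lab[a & (lab > 0)]))
    ids_b = set(np.unique(lab[b & (lab > 0)]))
    return bool(ids_a & ids_b)


def _pruned_skeleton(body: np.ndarray, max_iter: int) -> np.ndarray:
    """Partial thinning: legs reduce to their 1-px skeleton immediately while
    thick structures (torso, wings) survive as shrunken blobs."""
    from skimage.morphology import thin

    return thin(body, max_num_iter=max_iter)


def detect_tapping(pair: FramePair, params: BehaviorParams | None = None) -> bool:
    """Six-step cascade deciding whether a male leg touches the female torso.

    1. the two bodies form one silhouette (touching);
    2. the torsos are still two regions (not touching);
    3. the male head is within 1 mm of the female tail;
    4. thin the silhouette (branch scale = ``skel_branch_px``), add the
       torsos and erode: a connection that disappears was a bare leg
       (-> step 5), one that survives is covered by a wing (-> step 6);
    5. clip the leg branches to outside the thick torso-and-wings area and
       reattach them to the torsos: tapping iff the branched torsos
       connect (leg on torso), not tapping iff they stay apart (leg only
       on a wing);
    6. multiply the silhouette by the raw image and three-class Otsu it:
       a leg under a translucent wing forms a middle-intensity bridge;
       tapping iff that bridge connects the two torsos.
    """
    p = params or BehaviorParams()
    body = np.asarray(pair.body_mask, bool)
    tm = np.asarray(pair.torso_male, bool)
    tf = np.asarray(pair.torso_female, bool)
    if not (body.any() and tm.any() and tf.any()):
        return False
    # steps 1-3: silhouettes touch, torsos do not, head near tail
    if _components(body).max() != 1:
        return False
    if _components(tm | tf).max() != 2:
        return False
    if _head_tail_distance_mm(pair.male, pair.female, pair.mm_per_px) >= p.contact_mm:
        return False
    # step 4: normalize leg width (thinning reduces any leg to its 1-px
    # skeleton while wide structures -- torso, wing blades -- stay thick),
    # then erode: a connection that survives is wing-covered
    skel = _pruned_skeleton(body, p.skel_branch_px)
    thick = ndimage.distance_transform_edt(body) > 1.5
    from skimage.morphology import closing

    wings_torso_area = closing(thick, disk(p.erode_radius))
    with_legs = skel | wings_torso_area | tm | tf
    eroded = erosion(with_legs, disk(p.erode_radius))
    still_connected = _connected(eroded, tm, tf)
    if not still_connected:
        # step 5: bare-leg situation -- leg on torso vs leg on wing
        leg_branch = (skel | tm | tf) & ~wings_torso_area
        branched = leg_branch | tm | tf
        branched = remove_small_objects(branched, max_size=p.denoise_px,
                                        connectivity=2)
        return _connected(branched, tm, tf)
    # step 6: leg hidden under a wing shows as a middle-intensity bridge
    if pair.raw_crop is None:
        return False
    gray = pair.raw_crop.gray()
    vals = gray[body]
    if np.ptp(vals) < 1:
        return False
    try:
        t0, t1 = threshold_multiotsu(vals, classes=3)
    except ValueError:
        return False
    # a leg under a translucent wing is darker than the wing alone; Otsu
    # may group that bridge with the middle class or, when the darkening is
    # strong, with the torso-dark class -- accept either as a connection
    for lo, hi in ((t0, t1), (-np.inf, t0)):
        cls = body & (gray > lo) & (gray <= hi)
        bridge = remove_small_objects(cls | tm | tf, max_size=p.denoise_px,
                                      connectivity=2)
        if _connected(bridge, tm, tf):
            return True
    return False


def detect_attempted_copulation(male: FlyPose, female: FlyPose,
                                std: EccentricityStandard,
                                mm_per_px: float,
                                contact_mm: float = 1.0) -> bool:
    """Bent-abdomen mounting: low male eccentricity close to the female tail."""
    if std is None:
        raise ValueError("eccentricity standard not calibrated")
    if male.eccentricity >= std.standard_value:
        return False
    return _head_tail_distance_mm(male, female, mm_per_px) < contact_mm


def calibrate_standard(eccentricities, mode: str = "auto",
                       manual_index: int | None = None,
                       factor: float = 0.9,
                       fps: float = 24.0,
                       warn_below: float = 0.7) -> EccentricityStandard:
    """Choose the straight-male reference eccentricity.

    ``manual``: the user points at a frame showing an unbent male.
    ``auto``: the 95th percentile of the male eccentricity over the first
    30 s of valid frames — a straight fly is maximally eccentric, so the
    upper percentile tracks the unbent shape without manual input.
    """
    ecc = np.asarray([e for e in eccentricities if e is not None and np.isfinite(e)],
                     float)
    if ecc.size == 0:
        raise ValueError("no valid frames to calibrate the eccentricity standard")
    if mode == "manual":
        if manual_index is None:
            raise ValueError("manual calibration requires a frame index")
        reference = float(np.asarray(eccentricities, float)[manual_index])
    elif mode == "auto":
        window = ecc[: int(round(30.0 * fps))]
        reference = float(np.percentile(window, 95))
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")
    std = EccentricityStandard(reference_eccentricity=reference, factor=factor)
    if reference < warn_below:
        import warnings

        warnings.warn(
            f"eccentricity reference {reference:.3f} < {warn_below}: the male "
            "may never have been straight during calibration", stacklevel=2)
    return std


# ---------------------------------------------------------------------------
# temporal logic


def collapse_priority(flags) -> str:
    """Reduce a set of raw flags to the single highest-priority candidate."""
    for b in PRIORITY:
        if b in flags:
            return b
    return NONE


def noise_filter(raw_flags_seq, params: BehaviorParams | None = None) -> list[str]:
    """Certify per-frame candidates with the more-than-5-of-12 rule.

    Each frame's flags collapse to one candidate by priority.  A behavior
    is certified at frame t when its candidate count in the causal
    12-frame window ending at t exceeds 5 (pro-rated at the sequence
    start); frames whose own candidate fails the bar inherit the previous
    certified label unless another behavior clears it.  A run of 12 or
    more consecutive frames with no recognized behavior at all is labeled
    "none" from its start; shorter quiescent stretches and uncertified
    frames keep the previous certified label.
    """
    p = params or BehaviorParams()
    cands = [collapse_priority(f) for f in raw_flags_seq]
    n = len(cands)
    certified: list[str | None] = [None] * n
    for t in range(n):
        lo = max(0, t - p.filter_window + 1)
        window = cands[lo:t + 1]
        avail = len(window)
        need = p.filter_min_hits * avail / p.filter_window
        counts: dict[str, int] = {}
        for c in window:
            if c != NONE:
                counts[c] = counts.get(c, 0) + 1
        qualifying = {b: k for b, k in counts.items() if k > need}
        if not qualifying:
            continue
        own = cands[t]
        if own in qualifying:
            certified[t] = own
        else:
            certified[t] = max(
                qualifying, key=lambda b: (qualifying[b], -PRIORITY.index(b)))
    # quiescence: runs of >= none_gap frames with no recognized behavior
    quiescent = [False] * n
    t = 0
    while t < n:
        if cands[t] != NONE:
            t += 1
            continue
        run = t
        while run < n and cands[run] == NONE:
            run += 1
        if run - t >= p.none_gap:
            for i in range(t, run):
                quiescent[i] = True
        t = run
    labels = [NONE] * n
    prev = NONE
    for t in range(n):
        if quiescent[t]:
            labels[t] = NONE
            prev = NONE
        elif certified[t] is not None:
            prev = certified[t]
            labels[t] = prev
        else:
            labels[t] = prev
    return labels


def promote_copulation(labels, fps: float,
                       cop_seconds: float = 30.0) -> list[str]:
    """Relabel sustained attempted copulation as copulation.

    A maximal run of attempted copulation strictly longer than
    ``cop_seconds`` becomes copulation from its start, and every frame
    after it to the end of the recording is copulation as well (post-
    copulation behavior is not analyzed).
    """
    labels = list(labels)
    n = len(labels)
    limit = cop_seconds * fps  # promoted when run length exceeds this
    t = 0
    while t < n:
        if labels[t] != ATTEMPTED:
            t += 1
            continue
        run = t
        while run < n and labels[run] == ATTEMPTED:
            run += 1
        if (run - t) > limit:
            return labels[:t] + [COPULATION] * (n - t)
        t = run
    return labels


def classify_sequence(pairs, std: EccentricityStandard,
                      params: BehaviorParams | None = None) -> list[BehaviorRecord]:
    """Raw flags -> priority -> noise filter -> copulation promotion."""
    p = params or BehaviorParams()
    records = []
    for pair in pairs:
        flags = set()
        if detect_singing(pair.male, p.singing_deg):
            flags.add(SINGING)
        if detect_orientation(pair.male, pair.female, p.orient_ext,
                              p.orient_halfangle):
            flags.add(ORIENTATION)
        if detect_tapping(pair, p):
            flags.add(TAPPING)
        if detect_attempted_copulation(pair.male, pair.female, std,
                                       pair.mm_per_px, p.contact_mm):
            flags.add(ATTEMPTED)
        records.append(BehaviorRecord(frame_index=pair.frame_index,
                                      raw_flags=flags))
    labels = noise_filter([r.raw_flags for r in records], p)
    fps = pairs[0].raw_crop.fps if pairs and pairs[0].raw_crop is not None else 24.0
    labels = promote_copulation(labels, fps, p.cop_seconds)
    for r, lab in zip(records, labels):
        r.label = lab
    return records
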