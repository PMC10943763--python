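"""Identity maintenance across frames, overlaps included.

Frame-to-frame identity uses constant-velocity (rectilinear) prediction
from the previous two positions; detections are assigned to the male or
female by minimizing total distance to the predictions.  When the two
silhouettes merge into one, the blob is split by spectral clustering on
pixel coordinates and the halves are assigned by proximity to the
predictions.  Motion prediction can swap identities during an overlap, so
on the first clean frame after separation each fly's torso is canonicalized
(rotated horizontal, head left), watershed-segmented into head / thorax /
abdomen, and compared to stored reference parts by the Dice coefficient:
a candidate matches a reference when max + min of the three per-part Dice
values exceeds 1.6.  A verified mismatch swaps the identities back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as sklabel
from skimage.measure import regionprops
from skimage.morphology import h_maxima
from skimage.segmentation import watershed
from skimage.transform import rotate as skrotate

MALE = "male"
FEMALE = "female"

DICE_SCORE_THRESHOLD = 1.6  # on max+min of the three per-part Dice values


@dataclass
class TorsoParts:
    """Head / thorax / abdomen masks of a canonicalized torso.

    The masks are disjoint, live on the aligned torso grid (major axis
    horizontal, head on the left) and are ordered left-to-right.
    """

    head_mask: np.ndarray
    thorax_mask: np.ndarray
    abdomen_mask: np.ndarray

    def parts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.head_mask, self.thorax_mask, self.abdomen_mask


@dataclass
class TrackState:
    """Per-identity motion history and verification bookkeeping."""

    positions: dict = field(default_factory=lambda: {MALE: [], FEMALE: []})
    references: dict = field(default_factory=lambda: {MALE: None, FEMALE: None})
    reference_areas: dict = field(default_factory=lambda: {MALE: None, FEMALE: None})
    overlap_active: bool = False
    pending_verification: bool = False
    frames_since_refresh: dict = field(default_factory=lambda: {MALE: 0, FEMALE: 0})

    def push_position(self, fly_id: str, pos) -> None:
        hist = self.positions[fly_id]
        hist.append((float(pos[0]), float(pos[1])))
        if len(hist) > 2:
            del hist[:-2]


def predict_position(state: TrackState, fly_id: str) -> tuple[float, float]:
    """Constant-velocity extrapolation from the last two positions.

    With fewer than two prior positions the last known position (or the
    origin if none) is returned.
    """
    hist = state.positions[fly_id]
    if len(hist) == 0:
        return (0.0, 0.0)
    if len(hist) == 1:
        return hist[-1]
    (r2, c2), (r1, c1) = hist[-2], hist[-1]
    return (2 * r1 - r2, 2 * c1 - c2)


def assign_identities(detections, state: TrackState, areas=None) -> dict:
    """Map detection indices to identities by distance to the predictions.

    Two detections: the assignment minimizing the total distance to the two
    predicted positions wins.  One detection: an overlap — both identities
    map to it and ``overlap_active`` is set.  More than two detections (in
    a two-fly arena these are spurious): the two largest by area are kept.
    """
    detections = [np.asarray(d, float) for d in detections]
    if len(detections) == 0:
        raise ValueError("no detections to assign")
    if len(detections) > 2:
        if areas is None:
            areas = [1.0] * len(detections)
        order = np.argsort(areas)[::-1][:2]
        keep = sorted(order.tolist())
        mapping = assign_identities([detections[i] for i in keep], state)
        return {keep[i]: v for i, v in mapping.items()}
    pm = np.asarray(predict_position(state, MALE))
    pf = np.asarray(predict_position(state, FEMALE))
    if len(detections) == 1:
        state.overlap_active = True
        return {0: (MALE, FEMALE)}
    d = detections
    straight = np.linalg.norm(d[0] - pm) + np.linalg.norm(d[1] - pf)
    swapped = np.linalg.norm(d[0] - pf) + np.linalg.norm(d[1] - pm)
    if state.overlap_active:
        state.overlap_active = False
        state.pending_verification = True
    if straight <= swapped:
        return {0: (MALE,), 1: (FEMALE,)}
    return {0: (FEMALE,), 1: (MALE,)}


def split_overlap(blob_mask: np.ndarray, seed: int = 0,
                  bandwidth_px: float | None = None,
                  min_fly_area: int = 120,
                  max_samples: int = 700) -> list[np.ndarray]:
    """Partition a merged two-fly blob into two pixel sets.

    Spectral clustering with a Gaussian affinity on pixel coordinates; on
    large blobs a deterministic subsample is clustered and the remaining
    pixels take the label of their nearest sampled pixel.  A blob smaller
    than twice the minimum fly area is treated as one fly fully occluding
    the other and returned whole as both sets.
    """
    blob_mask = np.asarray(blob_mask, bool)
    coords = np.column_stack(np.nonzero(blob_mask)).astype(float)
    n = len(coords)
    if n < 2 * min_fly_area:
        return [blob_mask.copy(), blob_mask.copy()]
    from sklearn.cluster import SpectralClustering
    from sklearn.neighbors import NearestNeighbors

    rng = np.random.default_rng(seed)
    if n > max_samples:
        idx = rng.choice(n, size=max_samples, replace=False)
        idx.sort()
        sample = coords[idx]
    else:
        sample = coords
    if bandwidth_px is None:
        # ~half a typical torso minor axis, estimated from the blob area
        bandwidth_px = max(3.0, 0.25 * np.sqrt(n / 2.0))
    gamma = 1.0 / (2.0 * bandwidth_px ** 2)
    sc = SpectralClustering(n_clusters=2, affinity="rbf", gamma=gamma,
                            random_state=seed, assign_labels="kmeans",
                            n_init=10)
    labels = sc.fit_predict(sample)
    if len(sample) < n:
        nn = NearestNeighbors(n_neighbors=1).fit(sample)
        _, ind = nn.kneighbors(coords)
        labels = labels[ind[:, 0]]
    masks = []
    for k in (0, 1):
        m = np.zeros(blob_mask.shape, bool)
        pts = coords[labels == k].astype(int)
        m[pts[:, 0], pts[:, 1]] = True
        masks.append(m)
    return masks


def assign_split_clusters(cluster_masks, state: TrackState) -> dict:
    """Give split-overlap clusters identities by proximity to predictions."""
    cents = []
    for m in cluster_masks:
        ys, xs = np.nonzero(m)
        cents.append((ys.mean(), xs.mean()))
    pm = np.asarray(predict_position(state, MALE))
    pf = np.asarray(predict_position(state, FEMALE))
    d0, d1 = np.asarray(cents[0]), np.asarray(cents[1])
    straight = np.linalg.norm(d0 - pm) + np.linalg.norm(d1 - pf)
    swapped = np.linalg.norm(d0 - pf) + np.linalg.norm(d1 - pm)
    return {MALE: 0, FEMALE: 1} if straight <= swapped else {MALE: 1, FEMALE: 0}


def canonicalize_torso(torso_mask: np.ndarray, head=None,
                       pad: int = 2) -> tuple[np.ndarray, bool]:
    """Rotate a torso horizontal with the head on the left and crop it.

    Returns ``(aligned mask, head_known)``.  Without a head point the mask
    is aligned by its axis only and flagged, leaving a 180-degree ambiguity
    that verification treats as deferred.
    """
    from .pose import fit_torso

    fit = fit_torso(torso_mask)
    angle = fit["axis_angle_deg"]
    c = fit["centroid"]
    # skimage.rotate is CCW in (x=col, y=row) screen coordinates, which is
    # CW in this package's convention; rotating by -angle makes the axis
    # horizontal.
    rot = skrotate(torso_mask.astype(float), -angle,
                   center=(c[1], c[0]), order=0, resize=False,
                   preserve_range=True) > 0.5
    head_known = head is not None
    if head_known:
        hvec = np.asarray(head, float) - np.asarray(c)
        axis = np.array([-np.sin(np.deg2rad(angle)), np.cos(np.deg2rad(angle))])
        if np.dot(hvec, axis) > 0:
            # axis direction points headward; after rotation head is on the
            # right -> flip columns so the head lands on the left
            rot = rot[:, ::-1]
    ys, xs = np.nonzero(rot)
    if len(ys) == 0:
        return np.zeros((1, 1), bool), head_known
    out = rot[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    if pad:
        out = np.pad(out, pad)
    return out, head_known


def segment_torso_parts(aligned: np.ndarray, h_fraction: float = 0.25,
                        _retry: bool = True) -> TorsoParts | None:
    """Watershed the aligned torso into head, thorax and abdomen.

    The Euclidean distance map of the torso interior (distance to the
    torso boundary) is negated so the three body lobes become basins;
    shallow maxima are suppressed at an automatically chosen depth
    ``h_fraction x max(distance)`` before seeding the watershed.  If fewer
    than three segments emerge the suppression is relaxed once.  Two
    segments (a headless fly's two-lobed torso) are accepted with an empty
    head mask — two headless torsos still match each other (empty vs empty
    head counts as identical) while a headless/headed pairing is penalized.
    Fewer than two segments returns ``None``: verification is deferred.
    """
    aligned = np.asarray(aligned, bool)
    if not aligned.any():
        return None
    dist = ndimage.distance_transform_edt(aligned)
    h = max(h_fraction * float(dist.max()), 1e-3)
    markers = sklabel(h_maxima(dist, h))
    if markers.max() < 3 and _retry:
        return segment_torso_parts(aligned, h_fraction / 2.0, _retry=False)
    if markers.max() < 2:
        return None
    ws = watershed(-dist, markers, mask=aligned)
    all_regions = regionprops(ws)
    n_parts = min(3, len(all_regions))
    regions = sorted(all_regions, key=lambda r: r.area, reverse=True)[:n_parts]
    regions.sort(key=lambda r: r.centroid[1])  # left to right: head first
    masks = []
    for r in regions:
        m = np.zeros(aligned.shape, bool)
        m[ws == r.label] = True
        masks.append(m)
    # fold any spurious extra segments into the nearest kept part so the
    # three parts always tile the torso exactly
    kept = {r.label for r in regions}
    cols = [r.centroid[1] for r in regions]
    for r in all_regions:
        if r.label in kept:
            continue
        j = int(np.argmin([abs(r.centroid[1] - c) for c in cols]))
        masks[j] |= ws == r.label
    if len(masks) == 2:
        masks = [np.zeros(aligned.shape, bool)] + masks
    return TorsoParts(head_mask=masks[0], thorax_mask=masks[1],
                      abdomen_mask=masks[2])


def dice(a: np.ndarray, b: np.ndarray, align: bool = False) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|) of two binary masks.

    Masks of different shapes are zero-padded to a common grid (array
    centers coinciding); with ``align`` each mask is instead shifted so its
    centroid sits at the grid center, making the score translation-
    invariant (used for torso-part comparison).  Two empty masks are
    defined as identical (Dice 1).
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    rows = max(a.shape[0], b.shape[0]) * 2 + 3
    cols = max(a.shape[1], b.shape[1]) * 2 + 3
    grid_c = np.array([rows // 2, cols // 2], float)

    def place(m):
        out = np.zeros((rows, cols), bool)
        ys, xs = np.nonzero(m)
        if align:
            off = grid_c - np.array([ys.mean(), xs.mean()])
        else:
            off = grid_c - np.array([m.shape[0] / 2.0, m.shape[1] / 2.0])
        ys2 = ys + int(round(off[0]))
        xs2 = xs + int(round(off[1]))
        out[ys2, xs2] = True
        return out

    pa, pb = place(a), place(b)
    inter = int((pa & pb).sum())
    return 2.0 * inter / (na + nb)


def parts_score(candidate: TorsoParts, reference: TorsoParts) -> tuple[float, tuple]:
    """max + min of the three per-part Dice values for a pairing."""
    ds = tuple(dice(c, r, align=True)
               for c, r in zip(candidate.parts(), reference.parts()))
    return max(ds) + min(ds), ds


def verify_identities(candidates: dict, references: dict) -> dict:
    """Resolve post-overlap identities by torso shape matching.

    ``candidates`` maps the motion-prediction identity of each separated
    fly to its TorsoParts; ``references`` holds the stored pre-overlap
    TorsoParts.  Both the straight and the swapped pairing are scored; a
    pairing is acceptable when *both* of its pairs score above 1.6.  If
    exactly one pairing is acceptable it is adopted (overriding motion
    prediction when it is the swapped one); otherwise the motion-prediction
    assignment stands and verification is retried on a later frame.

    Returns ``{"assignment": {male: candidate_key, ...}, "passed": bool,
    "swapped": bool, "scores": {...}}``.
    """
    out = {"assignment": {MALE: MALE, FEMALE: FEMALE},
           "passed": False, "swapped": False, "scores": {}}
    if any(references.get(k) is None for k in (MALE, FEMALE)):
        return out
    if any(candidates.get(k) is None for k in (MALE, FEMALE)):
        return out
    s_mm, d_mm = parts_score(candidates[MALE], references[MALE])
    s_ff, d_ff = parts_score(candidates[FEMALE], references[FEMALE])
    s_mf, d_mf = parts_score(candidates[MALE], references[FEMALE])
    s_fm, d_fm = parts_score(candidates[FEMALE], references[MALE])
    out["scores"] = {"straight": (s_mm, s_ff), "swapped": (s_mf, s_fm),
                     "dice_straight": (d_mm, d_ff), "dice_swapped": (d_mf, d_fm)}
    straight_ok = s_mm > DICE_SCORE_THRESHOLD and s_ff > DICE_SCORE_THRESHOLD
    swapped_ok = s_mf > DICE_SCORE_THRESHOLD and s_fm > DICE_SCORE_THRESHOLD
    if straight_ok and swapped_ok:
        # both pass: keep the better-scoring pairing
        if s_mf + s_fm > s_mm + s_ff:
            out["assignment"] = {MALE: FEMALE, FEMALE: MALE}
            out["swapped"] = True
        out["passed"] = True
    elif straight_ok:
        out["passed"] = True
    elif swapped_ok:
        out["assignment"] = {MALE: FEMALE, FEMALE: MALE}
        out["swapped"] = True
        out["passed"] = True
    return out


def posture_plausible(eccentricity: float, area: float,
                      reference_area: float | None) -> bool:
    """Skip verification in aberrant postures (e.g. wall climbing).

    The torso of a fly standing on the floor is an elongated blob of
    roughly stable area; verification is skipped when eccentricity leaves
    [0.5, 0.99] or the area departs from 0.5-2x the reference.
    """
    if not (0.5 <= eccentricity <= 0.99):
        return False
    if reference_area and not (0.5 * reference_area <= area <= 2.0 * reference_area):
        return False
    return True
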