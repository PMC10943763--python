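"""Decision-boundary recovery and benchmark runs.

Each ``recover_*`` function probes an implemented detector with synthetic
poses or label sequences and locates its decision boundary by bisection or
exhaustive sweep.  On a correctly configured system the recovered
boundaries equal the published defaults (30-degree singing angle, 2.5x /
±10-degree orientation sector, 1-mm contact distance, 0.9x eccentricity
standard, >5-of-12 certification, 12-frame quiescence gap, half-minute
copulation rule).  They are recovered from behavior, not read from the
configuration, so they double as an end-to-end sanity check of a rig's
settings.
"""

from __future__ import annotations

import numpy as np

from . import behavior as bh
from .geometry import unit_vector
from .pose import FlyPose

MM_PER_PX = 0.05  # 11-mm arena imaged across 220 px


def _pose(centroid=(100.0, 100.0), heading_deg=0.0, head_dist=20.0,
          theta_l=0.0, theta_r=0.0, eccentricity=0.95) -> FlyPose:
    c = np.asarray(centroid, float)
    h = unit_vector(heading_deg)
    return FlyPose(
        torso_centroid=tuple(c), body_centroid=tuple(c - 2 * h),
        head=tuple(c + head_dist * h), tail=tuple(c - head_dist * h),
        heading=h, major_axis_px=2 * head_dist, minor_axis_px=16.0,
        eccentricity=eccentricity, left_wing_angle=theta_l,
        right_wing_angle=theta_r)


def _bisect(predicate, lo: float, hi: float, tol: float = 1e-7) -> float:
    """Boundary where a monotone predicate flips False -> True."""
    assert not predicate(lo) and predicate(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def recover_singing_threshold_deg(params: bh.BehaviorParams | None = None) -> float:
    p = params or bh.BehaviorParams()
    return _bisect(lambda t: bh.detect_singing(_pose(theta_l=t), p.singing_deg),
                   0.0, 179.0)


def recover_orientation_extension(params: bh.BehaviorParams | None = None) -> float:
    p = params or bh.BehaviorParams()
    head_dist = 20.0
    male = _pose(head_dist=head_dist)

    def inside(d):
        female = _pose(centroid=(100.0, 100.0 + d))
        return bh.detect_orientation(male, female, p.orient_ext,
                                     p.orient_halfangle)

    boundary = _bisect(lambda d: not inside(d), 1.0, 500.0)
    return boundary / head_dist


def recover_orientation_half_angle_deg(params: bh.BehaviorParams | None = None) -> float:
    p = params or bh.BehaviorParams()
    male = _pose(head_dist=20.0)
    radius = 30.0

    def outside(a_deg):
        a = np.deg2rad(a_deg)
        female = _pose(centroid=(100.0 - radius * np.sin(a),
                                 100.0 + radius * np.cos(a)))
        return not bh.detect_orientation(male, female, p.orient_ext,
                                         p.orient_halfangle)

    return _bisect(outside, 0.0, 90.0)


def recover_contact_distance_mm(params: bh.BehaviorParams | None = None) -> float:
    p = params or bh.BehaviorParams()
    std = bh.EccentricityStandard(0.95, factor=p.ecc_factor)
    male = _pose(head_dist=20.0, eccentricity=0.5 * std.standard_value)

    def beyond(d_px):
        # female tail at d_px from the male head
        female = _pose(centroid=(100.0, 120.0 + d_px + 20.0))
        return not bh.detect_attempted_copulation(male, female, std,
                                                  MM_PER_PX, p.contact_mm)

    return _bisect(beyond, 0.1, 100.0) * MM_PER_PX


def recover_eccentricity_factor(params: bh.BehaviorParams | None = None,
                                reference: float = 0.95) -> float:
    p = params or bh.BehaviorParams()
    std = bh.EccentricityStandard(reference, factor=p.ecc_factor)
    female = _pose(centroid=(100.0, 125.0))  # tail 5 px from the male head

    def rejected(ecc):
        male = _pose(head_dist=20.0, eccentricity=ecc)
        return not bh.detect_attempted_copulation(male, female, std,
                                                  MM_PER_PX, p.contact_mm)

    return _bisect(rejected, 0.01, 0.999) / reference


def recover_filter_certification_hits(params: bh.BehaviorParams | None = None
                                      ) -> tuple[int, int]:
    """(window, max hits NOT certified): 'more than 5 of 12' -> (12, 5)."""
    p = params or bh.BehaviorParams()
    window = p.filter_window
    last_uncertified = 0
    for k in range(0, window + 1):
        flags = [set()] * window + [{bh.SINGING}] * k + [set()] * (window - k)
        labels = bh.noise_filter(flags, p)
        if bh.SINGING not in labels:
            last_uncertified = k
    return window, last_uncertified


def recover_none_gap_frames(params: bh.BehaviorParams | None = None) -> int:
    """Smallest quiescent gap that is labeled 'none' instead of inheriting."""
    p = params or bh.BehaviorParams()
    for gap in range(1, 4 * p.none_gap):
        flags = ([{bh.SINGING}] * 24 + [set()] * gap + [{bh.SINGING}] * 24)
        labels = bh.noise_filter(flags, p)
        if bh.NONE in labels:
            return gap
    raise RuntimeError("no gap length produced a 'none' label")


def recover_copulation_seconds(params: bh.BehaviorParams | None = None,
                               fps: float = 24.0) -> float:
    """Longest attempted-copulation run (in s) NOT promoted to copulation."""
    p = params or bh.BehaviorParams()
    lo, hi = 1, int(10 * p.cop_seconds * fps)
    while lo < hi:
        mid = (lo + hi) // 2
        labels = [bh.ATTEMPTED] * mid
        promoted = bh.COPULATION in bh.promote_copulation(
            labels, fps, p.cop_seconds)
        if promoted:
            hi = mid
        else:
            lo = mid + 1
    return (lo - 1) / fps


# ---------------------------------------------------------------------------
# benchmark runs on scripted fixtures


def identity_tracking_accuracy(n_frames: int = 500, n_overlaps: int = 5,
                               seed: int = 13) -> dict:
    """Fraction of separated frames with correct male/female assignment."""
    import pandas as pd

    from .config import PipelineConfig
    from .fixtures import render_sequence
    from .pipeline import run_pipeline
    from .scenarios import overlap_wander

    script = overlap_wander(n_frames=n_frames, n_overlaps=n_overlaps)
    frames, _ = render_sequence(script.scenes, seed=seed, fps=script.fps)
    result = run_pipeline(None, PipelineConfig(arena_count=1),
                          frames=frames)[0]
    df = pd.DataFrame(result.track_rows)
    offset = 10.0  # arena crop origin in the fixture frame
    ok = total = 0
    for f, truth in enumerate(script.intended):
        if truth["overlap"]:
            continue
        sub = df[df.frame == f]
        if len(sub) < 2:
            continue
        male = sub[sub.fly_id == "male"].iloc[0]
        d_true = np.hypot(male.row - (truth["male"][0] - offset),
                          male.col - (truth["male"][1] - offset))
        d_swap = np.hypot(male.row - (truth["female"][0] - offset),
                          male.col - (truth["female"][1] - offset))
        total += 1
        ok += d_true < d_swap
    return {"accuracy": ok / total if total else float("nan"),
            "frames_scored": total, "n_frames": n_frames}


def behavior_recognition_agreement(seed: int = 11) -> dict:
    """Per-frame agreement with the courtship scene library's script."""
    from .config import PipelineConfig
    from .fixtures import render_sequence
    from .pipeline import run_pipeline
    from .scenarios import courtship_library

    lib = courtship_library()
    frames, _ = render_sequence(lib.scenes, seed=seed, fps=lib.fps)
    result = run_pipeline(None, PipelineConfig(arena_count=1),
                          frames=frames)[0]
    labels = [b.label for b in result.behavior_records]
    agree = float(np.mean([a == b for a, b in zip(labels, lib.expected)]))
    return {"agreement": agree, "n_frames": len(lib.expected)}
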