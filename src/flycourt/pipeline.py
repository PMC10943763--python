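"""End-to-end orchestration: frames -> tracks -> behaviors -> analytics.

Per arena the pipeline runs: background model (first frame) -> silhouette
segmentation -> identity assignment (motion prediction, spectral splitting
during overlap, torso shape matching after separation) -> pose -> behavior
classification -> ethogram summaries.  All outputs are plain CSV/JSON plus
a manifest (config digest, seed, versions) sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import ethogram as eg
from . import identity as idn
from . import segmentation as seg
from .config import PipelineConfig
from .pose import FlyPose, measure_pose, pose_row
from .video_io import ArenaRegion, FrameImage, crop_arena, detect_arenas, read_frames

log = logging.getLogger("flycourt")

MALE, FEMALE = idn.MALE, idn.FEMALE


@dataclass
class ArenaResult:
    arena: ArenaRegion
    track_rows: list = field(default_factory=list)
    pose_rows: list = field(default_factory=list)
    behavior_records: list = field(default_factory=list)
    ethogram: eg.Ethogram | None = None
    proportions: dict | None = None
    transitions: eg.TransitionMatrix | None = None
    summary: dict | None = None
    gaps: list = field(default_factory=list)


def _fly_masks_from_detection(comp_mask, torso_pixels, wings_pixels):
    torso = torso_pixels & comp_mask
    wings = wings_pixels & comp_mask
    return torso, wings


def _safe_pose(torso, wings, body, prev_pose: FlyPose | None,
               frame_index: int):
    """Pose with graceful degradation: keep the previous pose geometry when
    the torso fit fails (fragmented or too-small mask)."""
    from .pose import PoseError

    try:
        prev_heading = prev_pose.heading if prev_pose is not None else None
        return measure_pose(torso, wings, body, previous_heading=prev_heading,
                            frame_index=frame_index), True
    except PoseError:
        if prev_pose is None:
            return None, False
        ys, xs = np.nonzero(torso if torso.any() else body)
        if len(ys) == 0:
            return prev_pose, False
        c = (float(ys.mean()), float(xs.mean()))
        shift = np.array(c) - np.array(prev_pose.torso_centroid)
        moved = FlyPose(
            torso_centroid=c,
            body_centroid=tuple(np.array(prev_pose.body_centroid) + shift),
            head=tuple(np.array(prev_pose.head) + shift),
            tail=tuple(np.array(prev_pose.tail) + shift),
            heading=prev_pose.heading,
            major_axis_px=prev_pose.major_axis_px,
            minor_axis_px=prev_pose.minor_axis_px,
            eccentricity=prev_pose.eccentricity,
            left_wing_angle=prev_pose.left_wing_angle,
            right_wing_angle=prev_pose.right_wing_angle,
            frame_index=frame_index,
            orientation_defined=prev_pose.orientation_defined,
            head_ambiguous=True,
        )
        return moved, False


class ArenaTracker:
    """Stateful per-arena processing of a frame stream."""

    def __init__(self, arena: ArenaRegion, config: PipelineConfig):
        self.arena = arena
        self.config = config
        self.params = config.seg.to_params()
        self.bparams = config.behavior.to_params(config.filter)
        self.state = idn.TrackState()
        self.background = None
        self.prev_pose: dict = {MALE: None, FEMALE: None}
        self.result = ArenaResult(arena=arena)
        self.pairs: list[bh.FramePair] = []
        self._initialized = False

    # -- identity plumbing -------------------------------------------------
    def _initial_assignment(self, detections):
        """First frame: the smaller torso is the male (sex size dimorphism)."""
        if len(detections) == 1:
            return {0: (MALE, FEMALE)}
        areas = [d["area"] for d in detections]
        order = np.argsort(areas)
        return {int(order[0]): (MALE,), int(order[1]): (FEMALE,)}

    def _detections(self, masks):
        """Connected silhouette components with their torso sub-masks."""
        from skimage.measure import label as sklabel

        body = masks["body"].pixels
        lab = sklabel(body, connectivity=2)
        dets = []
        min_area = max(self.params.min_object_px,
                       self.config.identity.min_fly_area_px)
        for i in range(1, lab.max() + 1):
            comp = lab == i
            # a component far below one fly's area is debris (a detached
            # wing fragment, reflection speck), not a fly
            if comp.sum() < min_area:
                continue
            torso, wings = _fly_masks_from_detection(
                comp, masks["torso"].pixels, masks["wings"].pixels)
            ref = torso if torso.any() else comp
            ys, xs = np.nonzero(ref)
            dets.append({"mask": comp, "torso": torso, "wings": wings,
                         "centroid": (ys.mean(), xs.mean()),
                         "area": int(comp.sum())})
        dets.sort(key=lambda d: d["area"], reverse=True)
        return dets[:2]

    def _update_references(self, fly_id, pose, torso_mask):
        parts_ok = idn.posture_plausible(
            pose.eccentricity, torso_mask.sum(),
            self.state.reference_areas[fly_id])
        if not parts_ok:
            return
        refresh = self.config.identity.reference_refresh_frames
        count = self.state.frames_since_refresh[fly_id]
        if self.state.references[fly_id] is not None and count < refresh:
            self.state.frames_since_refresh[fly_id] = count + 1
            return
        aligned, head_known = idn.canonicalize_torso(torso_mask, pose.head)
        if not head_known:
            return
        parts = idn.segment_torso_parts(
            aligned, self.config.identity.watershed_h_fraction)
        if parts is None:
            return
        self.state.references[fly_id] = parts
        self.state.reference_areas[fly_id] = float(torso_mask.sum())
        self.state.frames_since_refresh[fly_id] = 0

    def _verify_after_overlap(self, per_fly, frame_index):
        cands, areas = {}, {}
        for fly_id in (MALE, FEMALE):
            pose, torso = per_fly[fly_id]["pose"], per_fly[fly_id]["torso"]
            if pose is None or not torso.any():
                return None
            if not idn.posture_plausible(pose.eccentricity, torso.sum(),
                                         self.state.reference_areas[fly_id]):
                return None
            aligned, head_known = idn.canonicalize_torso(torso, pose.head)
            if not head_known:
                return None
            parts = idn.segment_torso_parts(
                aligned, self.config.identity.watershed_h_fraction)
            if parts is None:
                return None
            cands[fly_id] = parts
            areas[fly_id] = torso.sum()
        res = idn.verify_identities(cands, self.state.references)
        return res

    # -- main per-frame step -------------------------------------------------
    def process_frame(self, crop: FrameImage):
        cfg = self.config
        if self.background is None:
            self.background = seg.build_background(crop, self.params.bg_window_px)
        masks = seg.segment_frame(crop, self.background, self.params)
        dets = self._detections(masks)
        fi = crop.index
        if not dets:
            self.result.gaps.append({"frame": fi, "reason": "no detections"})
            return

        if not self._initialized:
            mapping = self._initial_assignment(dets)
            self._initialized = True
        else:
            mapping = idn.assign_identities(
                [d["centroid"] for d in dets], self.state,
                areas=[d["area"] for d in dets])

        per_fly = {}
        verified = False
        swapped = False
        if len(dets) == 1 and len(mapping[0]) == 2:
            # overlap: split the blob (or treat as full occlusion)
            self.state.overlap_active = True
            blob = dets[0]["mask"]
            halves = idn.split_overlap(
                blob, seed=cfg.seed,
                min_fly_area=cfg.identity.min_fly_area_px,
                max_samples=cfg.identity.spectral_max_samples)
            if halves[0] is halves[1] or (halves[0] == halves[1]).all():
                assign = {MALE: 0, FEMALE: 1}
            else:
                assign = idn.assign_split_clusters(halves, self.state)
            for fly_id in (MALE, FEMALE):
                m = halves[assign[fly_id]]
                torso = masks["torso"].pixels & m
                wings = masks["wings"].pixels & m
                pose, ok = _safe_pose(torso, wings, m,
                                      self.prev_pose[fly_id], fi)
                per_fly[fly_id] = {"pose": pose, "torso": torso,
                                   "wings": wings, "body": m, "ok": ok}
        else:
            for di, ids in mapping.items():
                for fly_id in ids:
                    d = dets[di]
                    pose, ok = _safe_pose(d["torso"], d["wings"], d["mask"],
                                          self.prev_pose[fly_id], fi)
                    per_fly[fly_id] = {"pose": pose, "torso": d["torso"],
                                       "wings": d["wings"], "body": d["mask"],
                                       "ok": ok}
            if self.state.pending_verification and len(dets) == 2:
                res = self._verify_after_overlap(per_fly, fi)
                if res is not None and res["passed"]:
                    verified = True
                    self.state.pending_verification = False
                    if res["swapped"]:
                        swapped = True
                        per_fly = {MALE: per_fly[FEMALE],
                                   FEMALE: per_fly[MALE]}
                        for key in ("positions", "references",
                                    "reference_areas", "frames_since_refresh"):
                            d = getattr(self.state, key)
                            d[MALE], d[FEMALE] = d[FEMALE], d[MALE]
                        self.prev_pose[MALE], self.prev_pose[FEMALE] = (
                            self.prev_pose[FEMALE], self.prev_pose[MALE])

        for fly_id in (MALE, FEMALE):
            info = per_fly.get(fly_id)
            if info is None or info["pose"] is None:
                self.result.gaps.append({"frame": fi, "fly": fly_id,
                                         "reason": "pose failure"})
                return
            pose = info["pose"]
            self.state.push_position(fly_id, pose.torso_centroid)
            self.prev_pose[fly_id] = pose
            if len(dets) == 2 and info["ok"]:
                self._update_references(fly_id, pose, info["torso"])
            self.result.pose_rows.append(pose_row(pose, fly_id))
            self.result.track_rows.append({
                "frame": fi, "fly_id": fly_id,
                "row": pose.torso_centroid[0], "col": pose.torso_centroid[1],
                "overlap_active": len(dets) == 1,
                "verified_this_frame": verified,
                "swapped_this_frame": swapped,
            })

        pair = bh.FramePair(
            male=per_fly[MALE]["pose"], female=per_fly[FEMALE]["pose"],
            body_mask=masks["body"].pixels,
            torso_male=per_fly[MALE]["torso"],
            torso_female=per_fly[FEMALE]["torso"],
            wings_mask=masks["wings"].pixels,
            raw_crop=crop, mm_per_px=self.arena.mm_per_px,
            frame_index=fi)
        self.pairs.append(pair)

    # -- wrap-up -------------------------------------------------------------
    def finalize(self) -> ArenaResult:
        cfg = self.config
        if not self.pairs:
            return self.result
        fps = self.pairs[0].raw_crop.fps
        eccs = [p.male.eccentricity for p in self.pairs]
        cal = cfg.calibration
        std = bh.calibrate_standard(
            eccs, mode=cal.mode, manual_index=cal.manual_frame,
            factor=cfg.behavior.ecc_factor, fps=fps)
        records = bh.classify_sequence(self.pairs, std, self.bparams)
        self.result.behavior_records = records
        labels = [r.label for r in records]
        eth = eg.Ethogram(labels=labels, fps=fps).with_window(
            cfg.window_mode, cfg.window_seconds)
        self.result.ethogram = eth
        self.result.proportions = eg.element_proportions(eth)
        self.result.transitions = eg.transition_matrix(eth)
        self.result.summary = eg.courtship_pattern_summary(
            self.result.proportions, self.result.transitions,
            total_courtship_s=eg.total_courtship_time(eth))
        return self.result


def run_pipeline(source, config: PipelineConfig | None = None,
                 out_dir=None, frames=None) -> list[ArenaResult]:
    """Run the full pipeline on a video/image-sequence source.

    ``frames`` may supply an in-memory list of FrameImage instead of a
    source path.  Returns one ArenaResult per detected arena; when
    ``out_dir`` is given all CSV/JSON outputs and the run manifest are
    written beneath it (one subdirectory per arena).
    """
    config = config or PipelineConfig()
    if frames is None:
        frames = list(read_frames(source, fps=config.fps_override))
    if not frames:
        raise ValueError("no frames to process")
    log.info(json.dumps({"stage": "read", "frames": len(frames)}))
    arenas = detect_arenas(frames[0], expected_count=config.arena_count,
                           radius_range_px=config.radius_range_px)
    log.info(json.dumps({"stage": "arenas", "count": len(arenas)}))
    results = []
    for arena in arenas:
        tracker = ArenaTracker(arena, config)
        for fr in frames:
            try:
                tracker.process_frame(crop_arena(fr, arena))
            except Exception as exc:  # keep going; record the gap
                tracker.result.gaps.append(
                    {"frame": fr.index, "arena": arena.arena_id,
                     "reason": repr(exc)})
        results.append(tracker.finalize())
        log.info(json.dumps({"stage": "arena_done", "arena": arena.arena_id,
                             "frames": len(tracker.pairs),
                             "gaps": len(tracker.result.gaps)}))
    if out_dir is not None:
        write_outputs(results, config, Path(out_dir))
    return results


def write_outputs(results, config: PipelineConfig, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import flycourt

    manifest = {
        "config": config.model_dump(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": {"flycourt": flycourt.__version__,
                     "numpy": np.__version__},
        "arenas": [{"id": r.arena.arena_id, "center": list(r.arena.center),
                    "radius": r.arena.radius,
                    "mm_per_px": r.arena.mm_per_px} for r in results],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
    for r in results:
        adir = out_dir / f"arena_{r.arena.arena_id}"
        adir.mkdir(exist_ok=True)
        pd.DataFrame(r.track_rows).to_csv(adir / "track.csv", index=False)
        pd.DataFrame(r.pose_rows).to_csv(adir / "pose.csv", index=False)
        beh = pd.DataFrame({
            "frame": [b.frame_index for b in r.behavior_records],
            "raw_flags": [";".join(sorted(b.raw_flags))
                          for b in r.behavior_records],
            "label": [b.label for b in r.behavior_records],
        })
        beh.to_csv(adir / "behavior.csv", index=False)
        if r.ethogram is not None:
            pd.DataFrame({"frame": range(len(r.ethogram.labels)),
                          "label": r.ethogram.labels}).to_csv(
                adir / "ethogram.csv", index=False)
            pd.DataFrame([r.proportions]).to_csv(
                adir / "proportions.csv", index=False)
            r.transitions.to_frame("counts").to_csv(
                adir / "transition_counts.csv")
            r.transitions.to_frame("probabilities").to_csv(
                adir / "transition_probabilities.csv")
            eg.write_summary_json(r.summary, adir / "summary.json")


def annotate_video(source, results: list[ArenaResult], out_dir,
                   frames=None) -> list[Path]:
    """Overlay identities, headings, wingtips and labels on the frames.

    Writes an annotated PNG sequence; returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if frames is None:
        frames = list(read_frames(source))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_frame = {}
    by_frame_labels = {}
    for r in results:
        for row in r.track_rows:
            by_frame.setdefault(row["frame"], []).append((r, row))
        by_frame_labels.update(
            {b.frame_index: b.label for b in r.behavior_records})
    paths = []
    for fr in frames:
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(fr.pixels)
        for r, row in by_frame.get(fr.index, []):
            c0, r0 = r.arena.center[1] - r.arena.radius, r.arena.center[0] - r.arena.radius
            color = "tab:blue" if row["fly_id"] == MALE else "tab:red"
            ax.plot(row["col"] + c0, row["row"] + r0, "o", color=color,
                    markersize=4)
            ax.annotate(row["fly_id"][0].upper(),
                        (row["col"] + c0, row["row"] + r0), color=color)
        lab = by_frame_labels.get(fr.index) if results else None
        if lab:
            ax.set_title(lab)
        ax.axis("off")
        p = out_dir / f"annotated_{fr.index:05d}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    if len(paths) != len(frames):
        raise RuntimeError("frame-count mismatch in annotation")
    return paths
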