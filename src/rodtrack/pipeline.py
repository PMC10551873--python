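"""End-to-end pipeline: segment -> detect -> link -> kinematics.

``run_pipeline`` chains the stages over a video, writes every
intermediate product (heatmaps, detections.csv, tracks.csv,
kinematics.csv, summaries.csv, a trajectory overlay image and a run
manifest) into the output directory, and returns the in-memory
results.  Setting ``ground_truth_masks`` bypasses the network entirely
and feeds the masks straight into detection, which makes the tracking
back-end testable independently of segmentation quality.

``evaluate_against_ground_truth`` scores a pipeline run against the
simulator's true trajectories: detection recall/precision at a match
radius, identity-swap count, and per-motor speed and angular-velocity
errors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .config import PipelineConfig
from .detect import Detection, binarize, extract_instances
from .io import (VideoSource, write_detections, write_frames_tiff,
                 write_kinematics, write_summaries, write_tracks)
from .kinematics import KinematicsSample, TrackSummary, compute_kinematics, summarize
from .link import Track, build_trajectories
from .segnet import UNet, load_checkpoint, predict
from .synthdata import GroundTruthTrajectory

logger = logging.getLogger("rodtrack")

__all__ = ["PipelineResult", "run_pipeline", "evaluate_against_ground_truth"]


@dataclass
class PipelineResult:
    heatmaps: list[np.ndarray]
    detections: list[Detection]
    tracks: list[Track]
    samples_by_track: list[list[KinematicsSample]]
    summaries: list[TrackSummary]
    output_dir: Optional[Path] = None


def _overlay(frames: np.ndarray, tracks: Sequence[Track]) -> list[np.ndarray]:
    """Burn each track's path-so-far into every frame (white polyline)."""
    from skimage.draw import line as sk_line

    h, w = frames[0].shape
    out = []
    for f_idx, frame in enumerate(frames):
        canvas = np.asarray(frame, dtype=np.float32).copy()
        for t in tracks:
            pts = [(int(round(d.y)), int(round(d.x)))
                   for d in t.detections if d.frame_index <= f_idx]
            for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
                rr, cc = sk_line(y0, x0, y1, x1)
                ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                canvas[rr[ok], cc[ok]] = 1.0
        out.append(canvas)
    return out


def run_pipeline(config: PipelineConfig,
                 video: VideoSource | np.ndarray,
                 model: UNet | str | Path | None = None,
                 ground_truth_masks: Optional[Sequence[np.ndarray]] = None,
                 output_dir: str | Path | None = None) -> PipelineResult:
    """Run segmentation through kinematics over a video.

    ``model`` is a U-Net instance or a checkpoint path; it is only
    needed when ``ground_truth_masks`` is not given.  When an output
    directory is set (explicitly or via the config) all intermediates
    and a manifest are written there.
    """
    frames = video.frames if isinstance(video, VideoSource) else np.asarray(video)
    out = Path(output_dir) if output_dir is not None else (
        Path(config.output_dir) if config.output_dir else None)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if ground_truth_masks is not None:
        logger.info("segment: using %d ground-truth masks (network bypassed)",
                    len(ground_truth_masks))
        if len(ground_truth_masks) != len(frames):
            raise ValueError("one ground-truth mask per frame required")
        heatmaps = [np.asarray(m, dtype=np.float32) for m in ground_truth_masks]
    else:
        if model is None:
            raise ValueError("a model (or ground_truth_masks) is required")
        if not isinstance(model, UNet):
            model = load_checkpoint(model)
        logger.info("segment: running U-Net over %d frames", len(frames))
        try:
            heatmaps = predict(model, frames, batch_size=8)
        except ValueError as e:
            raise RuntimeError(f"stage 'segment' failed: {e}") from e

    detections: list[Detection] = []
    for i, hm in enumerate(heatmaps):
        try:
            mask = binarize(hm, config.detect.binarize_threshold)
            detections.extend(extract_instances(mask, config.detect,
                                                frame_index=i, weights=hm))
        except ValueError as e:
            raise RuntimeError(f"stage 'detect' failed at frame {i}: {e}") from e
    logger.info("detect: %d detections over %d frames",
                len(detections), len(frames))

    tracks = build_trajectories(detections, config.link)
    logger.info("link: %d tracks", len(tracks))

    samples_by_track = [compute_kinematics(t, config.calibration)
                        for t in tracks if len(t) >= 2]
    summaries, hists = (summarize(samples_by_track)
                        if samples_by_track else ([], {}))
    logger.info("kinematics: %d tracks with samples", len(samples_by_track))

    if out is not None:
        write_frames_tiff(heatmaps, out / "heatmaps.tiff")
        write_detections(detections, out / "detections.csv")
        write_tracks(tracks, out / "tracks.csv")
        write_kinematics(samples_by_track, out / "kinematics.csv")
        write_summaries(summaries, out / "summaries.csv")
        if hists:
            from .io import plot_histograms

            plot_histograms(hists, out / "histograms.png")
        if len(frames):
            write_frames_tiff(_overlay(frames, tracks), out / "overlay.tiff")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "n_frames": int(len(frames)),
            "used_ground_truth_masks": ground_truth_masks is not None,
            "config": config.to_dict(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(heatmaps=list(heatmaps), detections=detections,
                          tracks=tracks, samples_by_track=samples_by_track,
                          summaries=summaries, output_dir=out)


# ----------------------------------------------------------------- scoring

@dataclass
class GroundTruthScore:
    recall: float
    precision: float
    identity_swaps: int
    n_tracks: int
    speed_errors: dict[int, float] = field(default_factory=dict)   # motor -> rel err
    omega_errors: dict[int, float] = field(default_factory=dict)
    track_to_motor: dict[int, int] = field(default_factory=dict)


def _nearest_motor(det: Detection, poses_by_frame, radius: float):
    best, best_d = None, radius
    for mid, (x, y) in poses_by_frame.get(det.frame_index, {}).items():
        d = np.hypot(det.x - x, det.y - y)
        if d <= best_d:
            best, best_d = mid, d
    return best


def evaluate_against_ground_truth(
        result: PipelineResult,
        trajectories: Sequence[GroundTruthTrajectory],
        px_size: float, frame_rate: float,
        match_radius_px: float = 3.0) -> GroundTruthScore:
    """Score detections and tracks against simulator ground truth.

    A detection is a true positive when a true motor lies within
    ``match_radius_px``.  An identity swap is a transition inside one
    track between different matched motors.  Speed/omega errors compare
    each track's mean v (and mean |omega|) with the matched motor's
    true ``v * px_size * frame_rate`` (``|omega| * frame_rate``);
    tracks of motors with zero true speed or omega are skipped for the
    corresponding relative error.

    The recovered angular speed is ``|mean(omega_i)|`` -- the sign of
    omega is consistent along a track, and averaging signed steps
    before taking the magnitude avoids the upward rectification bias
    that ``mean(|omega_i|)`` suffers when per-step orientation noise is
    comparable to the per-frame rotation.
    """
    poses_by_frame: dict[int, dict[int, tuple[float, float]]] = {}
    true_motion: dict[int, tuple[float, float]] = {}
    n_true = 0
    for traj in trajectories:
        for frame, pose in traj.poses:
            poses_by_frame.setdefault(frame, {})[traj.motor_id] = (pose.x, pose.y)
            n_true += 1
        if traj.poses:
            p = traj.poses[0][1]
            true_motion[traj.motor_id] = (p.speed_v, p.omega)

    matched = [(_nearest_motor(d, poses_by_frame, match_radius_px), d)
               for d in result.detections]
    tp = sum(1 for mid, _ in matched if mid is not None)
    precision = tp / len(matched) if matched else 0.0
    # each (frame, motor) can be hit at most once for recall
    hit = {(d.frame_index, mid) for mid, d in matched if mid is not None}
    recall = len(hit) / n_true if n_true else 0.0

    swaps = 0
    speed_err, omega_err, assign = {}, {}, {}
    for track in result.tracks:
        ids = [_nearest_motor(d, poses_by_frame, match_radius_px)
               for d in track.detections]
        ids = [i for i in ids if i is not None]
        if not ids:
            continue
        swaps += sum(1 for a, b in zip(ids[:-1], ids[1:]) if a != b)
        majority = max(set(ids), key=ids.count)
        assign[track.track_id] = majority
        v_true, om_true = true_motion[majority]
        samples = next((s for s in result.samples_by_track
                        if s and s[0].track_id == track.track_id), None)
        if samples is None:
            continue
        if v_true > 0:
            v_mean = float(np.mean([s.v for s in samples]))
            speed_err[track.track_id] = (
                v_mean / (v_true * px_size * frame_rate) - 1.0)
        if om_true != 0:
            om_mean = abs(float(np.mean([s.omega for s in samples])))
            omega_err[track.track_id] = (
                om_mean / (abs(om_true) * frame_rate) - 1.0)

    return GroundTruthScore(recall=recall, precision=precision,
                            identity_swaps=swaps, n_tracks=len(result.tracks),
                            speed_errors=speed_err, omega_errors=omega_err,
                            track_to_motor=assign)
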