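"""Reading and writing the pipeline's on-disk formats.

Video input: multi-page grayscale TIFF or a directory of PNG/TIFF
frames (lexicographic filename order).  RGB input is averaged to
grayscale; integer bit depths are rescaled to [0, 1].

Tabular outputs are CSV via pandas, one schema per stage:

* detections.csv: frame, x_px, y_px, theta_rad, area_px2, aspect_ratio
* tracks.csv:     track_id, frame, x_px, y_px, theta_rad
* kinematics.csv: track_id, frame, t_s, x_um, y_um, theta_rad,
                  v_um_per_s, omega_rad_per_s, gap_flag
* summaries.csv:  track_id, mean_v, sd_v, mean_omega, sd_omega,
                  path_length_um, duration_s, n_samples
* trajectories.csv (ground truth): motor_id, frame, x_px, y_px,
                  phi_rad, v_px_per_frame, omega_rad_per_frame

Every writer has a matching reader so downstream stages can start from
files produced by upstream CLI invocations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .detect import Detection
from .kinematics import KinematicsSample, TrackSummary
from .link import Track
from .synthdata import GroundTruthTrajectory

__all__ = [
    "VideoSource",
    "read_video",
    "write_frames_tiff",
    "write_png_sequence",
    "write_detections",
    "read_detections",
    "write_tracks",
    "read_tracks",
    "write_kinematics",
    "write_summaries",
    "write_trajectories",
    "read_trajectories",
]

_FRAME_EXTS = (".png", ".tif", ".tiff")


@dataclass
class VideoSource:
    """An in-memory grayscale video, frames in [0, 1]."""

    frames: np.ndarray  # (N, H, W) float32
    path: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _to_gray01(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:  # RGB(A): average the color channels
        img = img[..., :3].mean(axis=-1)
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float32) / np.iinfo(img.dtype).max
    return np.clip(img.astype(np.float32), 0.0, 1.0)


def read_video(path: str | Path) -> VideoSource:
    """Load a multi-page TIFF, a single image, or a frame directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise ValueError(f"no frame files (PNG/TIFF) found in {path}")
        frames = [_to_gray01(iio.imread(f)) for f in files]
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [_to_gray01(f) for f in stack]
    elif path.suffix.lower() == ".png":
        frames = [_to_gray01(iio.imread(path))]
    else:
        raise ValueError(f"unsupported video container: {path.suffix!r} "
                         "(expected .tif/.tiff, .png, or a directory)")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"frames have mixed sizes: {sorted(shapes)}")
    return VideoSource(frames=np.stack(frames), path=str(path))


def write_frames_tiff(frames: Sequence[np.ndarray], path: str | Path,
                      as_uint8: bool = False) -> None:
    stack = np.stack([np.asarray(f, dtype=np.float32) for f in frames])
    if as_uint8:
        stack = np.clip(np.round(stack * 255), 0, 255).astype(np.uint8)
    # one grayscale page per frame (a 3-frame stack is not RGB)
    tifffile.imwrite(path, stack, photometric="minisblack")


def write_png_sequence(frames: Sequence[np.ndarray], out_dir: str | Path,
                       prefix: str = "frame") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, f in enumerate(frames):
        img = np.clip(np.round(np.asarray(f, dtype=float) * 255), 0, 255)
        p = out_dir / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, img.astype(np.uint8))
        paths.append(p)
    return paths


def plot_histograms(hists, path: str | Path) -> None:
    """Render the pooled / per-track v and omega histograms to one PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    titles = {"v_pooled": "v, all samples (um/s)",
              "omega_pooled": "omega, all samples (rad/s)",
              "v_track_means": "v, track means (um/s)",
              "omega_track_means": "omega, track means (rad/s)"}
    fig, axes = plt.subplots(2, 2, figsize=(8, 6))
    for ax, key in zip(axes.ravel(), titles):
        counts, edges = hists[key]
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
               edgecolor="black", linewidth=0.3)
        ax.set_title(titles[key], fontsize=9)
        ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ------------------------------------------------------------------ tables

def write_detections(detections: Sequence[Detection], path: str | Path) -> None:
    pd.DataFrame([{
        "frame": d.frame_index, "x_px": d.x, "y_px": d.y,
        "theta_rad": d.theta_axial, "area_px2": d.area,
        "aspect_ratio": d.aspect_ratio,
    } for d in detections]).to_csv(path, index=False)


def read_detections(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path)
    return [Detection(int(r.frame), float(r.x_px), float(r.y_px),
                      float(r.theta_rad), float(r.area_px2),
                      float(r.aspect_ratio))
            for r in df.itertuples()]


def write_tracks(tracks: Sequence[Track], path: str | Path) -> None:
    rows = []
    for t in tracks:
        for d in t.detections:
            rows.append({"track_id": t.track_id, "frame": d.frame_index,
                         "x_px": d.x, "y_px": d.y, "theta_rad": d.theta_axial})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks: dict[int, Track] = {}
    for r in df.itertuples():
        tid = int(r.track_id)
        det = Detection(int(r.frame), float(r.x_px), float(r.y_px),
                        float(r.theta_rad), area=float("nan"),
                        aspect_ratio=float("nan"))
        tracks.setdefault(tid, Track(track_id=tid)).detections.append(det)
    out = sorted(tracks.values(), key=lambda t: t.track_id)
    for t in out:
        t.detections.sort(key=lambda d: d.frame_index)
        t.active = False
    return out


def write_kinematics(samples_by_track: Sequence[Sequence[KinematicsSample]],
                     path: str | Path) -> None:
    rows = []
    for samples in samples_by_track:
        for s in samples:
            rows.append({
                "track_id": s.track_id, "frame": s.frame_index, "t_s": s.t,
                "x_um": s.x, "y_um": s.y, "theta_rad": s.theta,
                "v_um_per_s": s.v, "omega_rad_per_s": s.omega,
                "gap_flag": int(s.gap > 1),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summaries(summaries: Sequence[TrackSummary], path: str | Path) -> None:
    pd.DataFrame([{
        "track_id": s.track_id, "mean_v": s.mean_v, "sd_v": s.sd_v,
        "mean_omega": s.mean_omega, "sd_omega": s.sd_omega,
        "path_length_um": s.path_length, "duration_s": s.duration,
        "n_samples": s.n_samples,
    } for s in summaries]).to_csv(path, index=False)


def write_trajectories(trajectories: Sequence[GroundTruthTrajectory],
                       path: str | Path) -> None:
    rows = []
    for traj in trajectories:
        for frame, pose in traj.poses:
            rows.append({
                "motor_id": traj.motor_id, "frame": frame,
                "x_px": pose.x, "y_px": pose.y, "phi_rad": pose.heading_phi,
                "v_px_per_frame": pose.speed_v,
                "omega_rad_per_frame": pose.omega,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[GroundTruthTrajectory]:
    from .synthdata import MotorPose

    df = pd.read_csv(path)
    out: dict[int, GroundTruthTrajectory] = {}
    for r in df.itertuples():
        mid = int(r.motor_id)
        pose = MotorPose(float(r.x_px), float(r.y_px), float(r.phi_rad),
                         speed_v=float(r.v_px_per_frame),
                         omega=float(r.omega_rad_per_frame))
        out.setdefault(mid, GroundTruthTrajectory(mid)).poses.append(
            (int(r.frame), pose))
    return [out[k] for k in sorted(out)]
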