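"""Calibrated trajectory kinematics.

Converts linked pixel-space tracks into physical quantities using the
camera calibration (um/px, fps): positions in um, time in s,
instantaneous translational speed v = |dr| * px_size * fps / gap in
um/s, and instantaneous angular velocity omega from frame-to-frame
axial-orientation differences, in rad/s.

Because a rod's orientation is only defined modulo pi from its shape,
orientation differences are taken on the half-circle: the step from
theta1 to theta2 is the minimal signed rotation in (-pi/2, pi/2]
carrying one axis to the other.  The reported theta is unwrapped
cumulatively from these steps and its head/tail ambiguity is resolved
by the direction of motion whenever the motor moves faster than a
1 px/frame floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import CameraCalibration
from .link import Track

__all__ = [
    "KinematicsSample",
    "TrackSummary",
    "axial_difference",
    "compute_kinematics",
    "summarize",
]

SPEED_FLOOR_PX_PER_FRAME = 1.0  # below this, keep the previous head choice


@dataclass
class KinematicsSample:
    """One calibrated step (frame i -> i+1), stamped at the later frame."""

    track_id: int
    frame_index: int
    t: float        # s
    x: float        # um
    y: float        # um
    theta: float    # rad, unwrapped directed orientation
    v: float        # um/s
    omega: float    # rad/s
    gap: int = 1    # frames spanned by this step (>1 across missed frames)


@dataclass
class TrackSummary:
    track_id: int
    mean_v: float
    sd_v: float
    mean_omega: float
    sd_omega: float
    path_length: float  # um
    duration: float     # s
    n_samples: int


def axial_difference(theta1: float, theta2: float):
    """Minimal signed rotation (mod pi) from theta1 to theta2.

    Result lies in (-pi/2, pi/2]; adding it to theta1 gives an angle
    congruent to theta2 modulo pi.  Works elementwise on arrays.
    """
    d = (np.asarray(theta2) - np.asarray(theta1) + np.pi / 2) % np.pi - np.pi / 2
    d = np.where(d <= -np.pi / 2, d + np.pi, d)
    return float(d) if np.isscalar(theta1) and np.isscalar(theta2) else d


def _align_to_direction(theta_axial: float, direction: float) -> float:
    """Pick theta_axial or theta_axial + pi, whichever is within pi/2 of
    the displacement direction."""
    cand = (direction - theta_axial + np.pi) % (2 * np.pi) - np.pi
    return theta_axial if abs(cand) <= np.pi / 2 else theta_axial + np.pi


def compute_kinematics(track: Track, cal: CameraCalibration
                       ) -> list[KinematicsSample]:
    """Finite-difference kinematics of one track.

    For a step spanning g frames, v and omega are averages over the gap
    (divide by g); such steps carry gap > 1 in the output.  Produces
    len(track) - 1 samples.
    """
    dets = track.detections
    if len(dets) < 2:
        raise ValueError("track must contain at least 2 detections")

    # Directed initial orientation: align the axial angle with the first
    # displacement when the motor is actually moving.
    d0, d1 = dets[0], dets[1]
    disp = np.hypot(d1.x - d0.x, d1.y - d0.y)
    gap0 = d1.frame_index - d0.frame_index
    theta = d0.theta_axial
    if disp / max(gap0, 1) >= SPEED_FLOOR_PX_PER_FRAME:
        theta = _align_to_direction(d0.theta_axial,
                                    float(np.arctan2(d1.y - d0.y, d1.x - d0.x)))

    samples: list[KinematicsSample] = []
    for a, b in zip(dets[:-1], dets[1:]):
        g = b.frame_index - a.frame_index
        if g < 1:
            raise ValueError("frame indices must strictly increase")
        step = axial_difference(a.theta_axial, b.theta_axial)
        theta = theta + step
        dx, dy = b.x - a.x, b.y - a.y
        v = float(np.hypot(dx, dy) * cal.px_size * cal.frame_rate / g)
        omega = float(step * cal.frame_rate / g)
        samples.append(KinematicsSample(
            track_id=track.track_id,
            frame_index=b.frame_index,
            t=b.frame_index / cal.frame_rate,
            x=b.x * cal.px_size,
            y=b.y * cal.px_size,
            theta=float(theta),
            v=v,
            omega=omega,
            gap=g,
        ))
    return samples


def summarize(samples_by_track: Sequence[Sequence[KinematicsSample]],
              v_bin_width: float = 10.0,
              omega_bin_width: float = 0.5,
              ) -> tuple[list[TrackSummary], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-track statistics plus pooled histograms.

    Histograms are returned both over all instantaneous samples and
    over per-track means, as ``(counts, bin_edges)`` pairs keyed
    ``v_pooled``, ``omega_pooled``, ``v_track_means``,
    ``omega_track_means``.
    """
    if not samples_by_track:
        raise ValueError("no tracks to summarize")
    summaries = []
    all_v, all_omega = [], []
    for samples in samples_by_track:
        v = np.array([s.v for s in samples])
        om = np.array([s.omega for s in samples])
        t = np.array([s.t for s in samples])
        fps = _fps(samples)
        step_dt = np.array([s.gap for s in samples]) / fps
        summaries.append(TrackSummary(
            track_id=samples[0].track_id,
            mean_v=float(v.mean()), sd_v=float(v.std()),
            mean_omega=float(om.mean()), sd_omega=float(om.std()),
            path_length=float(np.sum(v * step_dt)),
            duration=float(t[-1] - t[0] + step_dt[0]),
            n_samples=len(samples),
        ))
        all_v.extend(v)
        all_omega.extend(om)

    def _hist(values, width):
        values = np.asarray(values, dtype=float)
        lo = min(0.0, float(values.min()))
        hi = float(values.max()) + width
        edges = np.arange(lo, hi + width, width)
        counts, edges = np.histogram(values, bins=edges)
        return counts, edges

    hists = {
        "v_pooled": _hist(all_v, v_bin_width),
        "omega_pooled": _hist(all_omega, omega_bin_width),
        "v_track_means": _hist([s.mean_v for s in summaries], v_bin_width),
        "omega_track_means": _hist([s.mean_omega for s in summaries],
                                   omega_bin_width),
    }
    return summaries, hists


def _fps(samples: Sequence[KinematicsSample]) -> float:
    # recover fps from the time stamps of any sample pair, falling back
    # to the step's own gap for a single sample
    s = samples[0]
    return s.frame_index / s.t if s.t > 0 else 1.0
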