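"""Frame-to-frame identity linking by minimum-cost assignment.

Detections in consecutive frames are matched by solving the bipartite
assignment problem with centroid Euclidean distance as cost (the
Hungarian problem; solved here via scipy's Jonker-Volgenant
implementation).  A distance gate forbids implausible jumps: the cost
matrix is augmented with per-track and per-detection "stay unmatched"
entries at exactly the gate cost, so a link more expensive than the
gate never forms.  Unmatched tracks coast for up to
``max_missed_frames`` frames before retiring; unmatched detections
open new tracks.  Short tracks are discarded at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import LinkConfig
from .detect import Detection

__all__ = ["Track", "solve_assignment", "link_frame", "build_trajectories"]

_BIG = 1e7  # forbidden-pairing cost in the augmented matrix


@dataclass
class Track:
    """An identity-linked, time-ordered sequence of detections."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)
    missed: int = 0
    active: bool = True

    @property
    def last(self) -> Detection:
        return self.detections[-1]

    def __len__(self) -> int:
        return len(self.detections)


def solve_assignment(cost: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-total-cost matching of size min(n, m).

    Ties between equal-cost optimal matchings are broken toward the
    lexicographically smallest (row, col) pairing by adding a
    deterministic index-ordered perturbation far below the cost scale.
    Rejects NaN and negative entries.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2:
        raise ValueError("cost matrix must be 2-D")
    if np.isnan(cost).any():
        raise ValueError("cost matrix contains NaN")
    if (cost < 0).any():
        raise ValueError("cost matrix contains negative entries")
    n, m = cost.shape
    if n == 0 or m == 0:
        return []
    scale = float(cost.max())
    eps = (scale if scale > 0 else 1.0) * 1e-12
    idx = np.arange(n)[:, None] * m + np.arange(m)[None, :]
    rows, cols = linear_sum_assignment(cost + eps * idx)
    return sorted(zip(rows.tolist(), cols.tolist()))


def link_frame(tracks: list[Track], detections: Sequence[Detection],
               config: LinkConfig, _next_id: list[int] | None = None
               ) -> list[Track]:
    """Extend active tracks with one frame's detections.

    Matching minimizes total centroid distance subject to the gate.
    Matched tracks absorb their detection and reset their miss counter;
    unmatched tracks age and retire past ``max_missed_frames``;
    unmatched detections seed new tracks.  Returns the full track list
    (including retired tracks).
    """
    detections = list(detections)
    if detections:
        frame = detections[0].frame_index
        bad = [d for d in detections if d.frame_index != frame]
        if bad:
            raise ValueError("detections span multiple frame indices")
        for t in tracks:
            if t.active and t.last.frame_index >= frame:
                raise ValueError(
                    f"track {t.track_id} already extends to frame "
                    f"{t.last.frame_index} >= {frame}")

    active = [t for t in tracks if t.active]
    n, m = len(active), len(detections)
    gate = config.gate_px

    matched_tracks: set[int] = set()
    matched_dets: set[int] = set()
    if n and m:
        dist = np.array([[np.hypot(t.last.x - d.x, t.last.y - d.y)
                          for d in detections] for t in active])
        # Augmented square matrix: every row (track) and column
        # (detection) may stay unmatched at exactly the gate cost.  The
        # gate stays flat while a track coasts: a coasting track is
        # already uncertain, so widening its search region would invite
        # captures of neighbouring motors.
        aug = np.full((n + m, m + n), _BIG)
        aug[:n, :m] = np.where(dist <= gate, dist, _BIG)
        aug[:n, m:] = np.where(np.eye(n, dtype=bool), gate, _BIG)
        aug[n:, :m] = np.where(np.eye(m, dtype=bool), gate, _BIG)
        aug[n:, m:] = 0.0
        for r, c in solve_assignment(aug):
            if r < n and c < m and dist[r, c] <= gate:
                matched_tracks.add(r)
                matched_dets.add(c)
                active[r].detections.append(detections[c])
                active[r].missed = 0

    for i, t in enumerate(active):
        if i not in matched_tracks:
            t.missed += 1
            if t.missed > config.max_missed_frames:
                t.active = False

    if _next_id is None:
        _next_id = [max((t.track_id for t in tracks), default=-1) + 1]
    for j, d in enumerate(detections):
        if j not in matched_dets:
            tracks.append(Track(track_id=_next_id[0], detections=[d]))
            _next_id[0] += 1
    return tracks


def build_trajectories(detections: Iterable[Detection],
                       config: LinkConfig | None = None) -> list[Track]:
    """Link a full video's detections into tracks.

    Detections are grouped by frame and processed in increasing frame
    order; tracks shorter than ``min_track_length`` are dropped.  The
    result is sorted by track_id.
    """
    config = config or LinkConfig()
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame_index, []).append(d)

    tracks: list[Track] = []
    next_id = [0]
    for frame in sorted(by_frame):
        tracks = link_frame(tracks, by_frame[frame], config, _next_id=next_id)
    for t in tracks:
        t.active = False
    kept = [t for t in tracks if len(t) >= config.min_track_length]
    return sorted(kept, key=lambda t: t.track_id)
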