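"""From heatmaps to per-frame micromotor instances.

The network's heatmap is thresholded, cleaned (outline masks are closed
and hole-filled so moments see the full rod), and labeled into
8-connected components.  Components are kept only if their area lies in
[min_area, max_area] and their moment-derived aspect ratio reaches
min_aspect_ratio -- this is where round bubble remnants are rejected,
since rods are elongated and bubbles are not.  Each surviving component
yields a Detection with its (optionally intensity-weighted) centroid
and the principal-axis orientation from central second moments.

Orientations are axial: a rod looks the same rotated by pi, so
theta_axial lives in [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .config import DetectConfig

__all__ = [
    "Detection",
    "binarize",
    "orientation_from_moments",
    "extract_instances",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class Detection:
    """One micromotor instance in one frame."""

    frame_index: int
    x: float          # centroid column, px
    y: float          # centroid row, px
    theta_axial: float  # principal axis, rad in [0, pi)
    area: float       # px^2
    aspect_ratio: float  # major/minor moment axis; inf when degenerate
    degenerate: bool = False


def binarize(heatmap: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixel = 1 iff heatmap >= threshold (closed lower bound)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(heatmap) >= threshold).astype(np.uint8)


def _second_moments(ys: np.ndarray, xs: np.ndarray,
                    weights: Optional[np.ndarray] = None):
    """Weighted centroid and central second moments of a pixel set."""
    if weights is None:
        weights = np.ones_like(xs, dtype=float)
    wsum = weights.sum()
    cx = float((weights * xs).sum() / wsum)
    cy = float((weights * ys).sum() / wsum)
    dx, dy = xs - cx, ys - cy
    mu20 = float((weights * dx * dx).sum() / wsum)
    mu02 = float((weights * dy * dy).sum() / wsum)
    mu11 = float((weights * dx * dy).sum() / wsum)
    return cx, cy, mu20, mu02, mu11


def orientation_from_moments(ys: np.ndarray, xs: np.ndarray,
                             weights: Optional[np.ndarray] = None
                             ) -> tuple[float, bool]:
    """Principal-axis orientation of a pixel set, in [0, pi).

    theta = 0.5 * atan2(2*mu11, mu20 - mu02) with mu_pq the central
    second moments (x = column, y = row).  Returns (theta, degenerate);
    degenerate is True for single-pixel or isotropic sets, for which
    theta defaults to 0.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2:
        return 0.0, True
    _, _, mu20, mu02, mu11 = _second_moments(ys, xs, weights)
    if mu20 == mu02 and mu11 == 0.0:
        return 0.0, True
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    return float(theta % np.pi), False


def _axis_lengths(mu20: float, mu02: float, mu11: float) -> tuple[float, float]:
    t = mu20 + mu02
    d = np.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11 ** 2)
    l1 = max((t + d) / 2.0, 0.0)
    l2 = max((t - d) / 2.0, 0.0)
    return 4.0 * np.sqrt(l1), 4.0 * np.sqrt(l2)


def extract_instances(mask: np.ndarray, config: Optional[DetectConfig] = None,
                      frame_index: int = 0,
                      weights: Optional[np.ndarray] = None) -> list[Detection]:
    """Label a binary mask and measure each surviving component.

    ``weights`` (e.g. the raw heatmap) makes centroids
    intensity-weighted; without it the plain pixel centroid is used.
    Outline-style masks are first morphologically closed (3x3) and
    hole-filled when ``config.fill_outlines`` is set.
    """
    config = config or DetectConfig()
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError(f"mask must be binary, found values {vals[:10]}")
    work = mask.astype(bool)
    if config.fill_outlines:
        work = ndimage.binary_closing(work, structure=_EIGHT)
        work = ndimage.binary_fill_holes(work)

    labels, n = ndimage.label(work, structure=_EIGHT)
    detections: list[Detection] = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        area = float(len(xs))
        if area < config.min_area or area > config.max_area:
            continue
        w = weights[ys, xs] if weights is not None else None
        cx, cy, mu20, mu02, mu11 = _second_moments(
            ys.astype(float), xs.astype(float), w)
        theta, degen = orientation_from_moments(ys, xs, w)
        major, minor = _axis_lengths(mu20, mu02, mu11)
        aspect = float("inf") if minor == 0 else major / minor
        if aspect < config.min_aspect_ratio:
            continue
        detections.append(Detection(frame_index, cx, cy, theta, area,
                                    aspect, degenerate=degen))
    return detections
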