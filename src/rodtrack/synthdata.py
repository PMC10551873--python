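"""Simulated bright-field microscopy of bubble-propelled rod micromotors.

Generates frames, paired ground-truth segmentation masks, and
ground-truth trajectories for training and validating the segmentation
and tracking stages.  A scene holds rod-shaped motors (capsule
footprints, ~10 px x 3 px at the default 1.53 um/px calibration),
small microbubbles trailing behind each rod opposite its heading (the
visible propulsion exhaust), and larger background bubbles.  Ground
truth covers the motors only: the network is meant to learn to ignore
every bubble.

Image formation is an explicit chain: rasterize objects onto a uniform
background, Gaussian blur (point-spread proxy), linear illumination
gradient, additive Gaussian noise, clip to [0, 1].

Coordinates are 0-based with x = column, y = row (origin top-left),
pixel centers at integer coordinates, and angles measured from the +x
axis toward +y (i.e. clockwise on screen, counterclockwise in matrix
coordinates).  Headings are full angles in [0, 2pi); the rod shape
itself is symmetric under heading -> heading + pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .config import OpticsConfig

__all__ = [
    "MotorPose",
    "BubbleSpec",
    "MotorGeometry",
    "Scene",
    "GroundTruthTrajectory",
    "sample_scene",
    "render_frame",
    "render_ground_truth",
    "simulate_video",
    "make_training_set",
    "capsule_mask",
]

_EDGE_MARGIN = 5.0  # px inset for initial placement


@dataclass
class MotorPose:
    """State of one rod micromotor.

    ``heading_phi`` is the direction of motion in [0, 2pi); the axial
    orientation observable from the shape alone is ``heading_phi mod pi``.
    ``speed_v`` is px/frame, ``omega`` rad/frame (signed, 0 = straight).
    """

    x: float
    y: float
    heading_phi: float
    length: float = 10.0
    width: float = 3.0
    speed_v: float = 0.0
    omega: float = 0.0

    def __post_init__(self):
        if not (self.length > self.width > 0):
            raise ValueError("require length > width > 0")
        if self.speed_v < 0:
            raise ValueError("speed_v must be >= 0")

    @property
    def theta_axial(self) -> float:
        return self.heading_phi % np.pi


@dataclass
class BubbleSpec:
    x: float
    y: float
    radius: float
    kind: Literal["background", "trailing"] = "background"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass
class MotorGeometry:
    """Normal distributions for rod dimensions, in px."""

    length_mean: float = 10.0
    length_sd: float = 1.0
    width_mean: float = 3.0
    width_sd: float = 0.3

    def __post_init__(self):
        if min(self.length_mean, self.width_mean) <= 0:
            raise ValueError("distribution means must be positive")
        if min(self.length_sd, self.width_sd) < 0:
            raise ValueError("distribution s.d. must be >= 0")


@dataclass
class Scene:
    """World state of a single frame."""

    frame_index: int = 0
    motors: list[MotorPose] = field(default_factory=list)
    bubbles: list[BubbleSpec] = field(default_factory=list)


@dataclass
class GroundTruthTrajectory:
    motor_id: int
    poses: list[tuple[int, MotorPose]] = field(default_factory=list)

    def frames(self) -> np.ndarray:
        return np.array([f for f, _ in self.poses], dtype=int)

    def xy(self) -> np.ndarray:
        return np.array([[p.x, p.y] for _, p in self.poses])


# ----------------------------------------------------------------- geometry

def _capsule_distance(shape: tuple[int, int], x: float, y: float,
                      phi: float, length: float, width: float) -> np.ndarray:
    """Distance from each pixel center to the capsule's spine segment."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - x, yy - y
    c, s = np.cos(phi), np.sin(phi)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    half = max((length - width) / 2.0, 0.0)
    uc = np.clip(u, -half, half)
    return np.hypot(u - uc, v)


def capsule_mask(shape: tuple[int, int], x: float, y: float, phi: float,
                 length: float, width: float, *, soft: bool = False) -> np.ndarray:
    """Rasterize a capsule (rod) footprint.

    ``soft`` returns fractional edge coverage (a ~1 px linear ramp);
    otherwise a binary pixel-center test against the half-width.
    """
    d = _capsule_distance(shape, x, y, phi, length, width)
    r = width / 2.0
    if soft:
        return np.clip(r + 0.5 - d, 0.0, 1.0)
    return (d <= r).astype(np.uint8)


def _ring_coverage(shape: tuple[int, int], x: float, y: float,
                   radius: float, rim: float = 1.0) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = np.hypot(xx - x, yy - y)
    return np.clip(rim / 2.0 + 0.5 - np.abs(d - radius), 0.0, 1.0)


# ----------------------------------------------------------------- sampling

def _trailing_bubbles(pose: MotorPose, rng: np.random.Generator) -> list[BubbleSpec]:
    """Seed 2-5 exhaust bubbles behind the rod's tail end.

    The trail runs opposite the heading with +-15 deg of angular jitter
    per step, successive bubbles roughly touching; radii are drawn
    around the rod width (+-30%).
    """
    n = int(rng.integers(2, 6))
    radii = pose.width * rng.uniform(0.7, 1.3, size=n)
    jitter = np.deg2rad(15.0)
    psi = pose.heading_phi + np.pi + rng.uniform(-jitter, jitter)
    px = pose.x + (pose.length / 2.0 + radii[0]) * np.cos(psi)
    py = pose.y + (pose.length / 2.0 + radii[0]) * np.sin(psi)
    bubbles = [BubbleSpec(px, py, float(radii[0]), kind="trailing")]
    for k in range(1, n):
        psi = pose.heading_phi + np.pi + rng.uniform(-jitter, jitter)
        step = (radii[k - 1] + radii[k]) * rng.uniform(0.9, 1.4)
        px += step * np.cos(psi)
        py += step * np.sin(psi)
        bubbles.append(BubbleSpec(float(px), float(py), float(radii[k]),
                                  kind="trailing"))
    return bubbles


def sample_scene(optics: OpticsConfig, n_motors: int,
                 n_background_bubbles: int,
                 motor_geom: Optional[MotorGeometry] = None,
                 seed: int = 0) -> Scene:
    """Draw a random scene.

    Motor and background-bubble positions are normal around the image
    center (s.d. = dims/4, clipped to a 5 px inset); headings uniform on
    [0, 2pi).  Each motor gets a trailing-bubble plume behind its tail.
    """
    if n_motors < 0 or n_background_bubbles < 0:
        raise ValueError("object counts must be >= 0")
    geom = motor_geom or MotorGeometry()
    rng = np.random.default_rng(seed)
    h, w = optics.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    def _pos():
        x = np.clip(rng.normal(cx, w / 4.0), _EDGE_MARGIN, w - 1 - _EDGE_MARGIN)
        y = np.clip(rng.normal(cy, h / 4.0), _EDGE_MARGIN, h - 1 - _EDGE_MARGIN)
        return float(x), float(y)

    motors, bubbles = [], []
    for _ in range(n_motors):
        x, y = _pos()
        phi = float(rng.uniform(0.0, 2.0 * np.pi))
        width = float(max(rng.normal(geom.width_mean, geom.width_sd), 1.0))
        length = float(max(rng.normal(geom.length_mean, geom.length_sd),
                           width + 1.0))
        pose = MotorPose(x, y, phi, length=length, width=width)
        motors.append(pose)
        bubbles.extend(_trailing_bubbles(pose, rng))
    for _ in range(n_background_bubbles):
        x, y = _pos()
        bubbles.append(BubbleSpec(x, y, float(rng.uniform(6.0, 14.0)),
                                  kind="background"))
    return Scene(frame_index=0, motors=motors, bubbles=bubbles)


# ---------------------------------------------------------------- rendering

def render_frame(scene: Scene, optics: OpticsConfig,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Render one frame: rasterize -> blur -> shade -> noise -> clip.

    Noise and the illumination-gradient direction are drawn from
    ``rng``; when omitted, a generator seeded by (optics.seed,
    scene.frame_index) is used, so the same scene renders identically
    every time.
    """
    if rng is None:
        rng = np.random.default_rng((optics.seed, scene.frame_index))
    shape = optics.shape
    img = np.full(shape, optics.background_level, dtype=float)

    for m in scene.motors:
        cov = capsule_mask(shape, m.x, m.y, m.heading_phi, m.length, m.width,
                           soft=True)
        img += optics.object_contrast * cov
    rim_contrast = abs(optics.object_contrast)
    for b in scene.bubbles:
        img += rim_contrast * _ring_coverage(shape, b.x, b.y, b.radius)

    if optics.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, optics.blur_sigma)

    if optics.illum_gradient_amp != 0:
        ang = rng.uniform(0.0, 2.0 * np.pi)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        ramp = ((xx / max(shape[1] - 1, 1) - 0.5) * np.cos(ang)
                + (yy / max(shape[0] - 1, 1) - 0.5) * np.sin(ang))
        img += optics.illum_gradient_amp * ramp

    if optics.noise_sigma > 0:
        img += rng.normal(0.0, optics.noise_sigma, size=shape)

    return np.clip(img, 0.0, 1.0).astype(np.float32)


def render_ground_truth(scene: Scene, optics: OpticsConfig,
                        mode: Literal["outline", "filled"] = "filled") -> np.ndarray:
    """Binary ground-truth mask of the motors; bubbles contribute nothing.

    ``filled`` marks the full capsule interiors; ``outline`` a 2-px-thick
    inner boundary band of the (merged) filled mask.
    """
    if mode not in ("outline", "filled"):
        raise ValueError(f"unknown mask mode: {mode!r}")
    shape = optics.shape
    filled = np.zeros(shape, dtype=bool)
    for m in scene.motors:
        filled |= capsule_mask(shape, m.x, m.y, m.heading_phi,
                               m.length, m.width).astype(bool)
    if mode == "filled":
        return filled.astype(np.uint8)
    eroded = ndimage.binary_erosion(filled, iterations=2)
    return (filled & ~eroded).astype(np.uint8)


# --------------------------------------------------------------- simulation

def _advance(pose: MotorPose, boundary: str, w: int, h: int) -> MotorPose:
    x = pose.x + pose.speed_v * np.cos(pose.heading_phi)
    y = pose.y + pose.speed_v * np.sin(pose.heading_phi)
    phi = (pose.heading_phi + pose.omega) % (2.0 * np.pi)
    if boundary == "wrap":
        x, y = x % w, y % h
    return replace(pose, x=float(x), y=float(y), heading_phi=float(phi))


def simulate_video(initial: Scene, n_frames: int,
                   motion: Optional[Sequence[tuple[float, float]]] = None,
                   optics: Optional[OpticsConfig] = None, seed: int = 0,
                   mask_mode: Literal["outline", "filled"] = "filled",
                   boundary: Literal["none", "wrap"] = "none",
                   render: bool = True):
    """Propagate a scene through time and render frames + ground truth.

    Per frame each motor's pose is recorded, then advanced by
    ``x += v cos(phi), y += v sin(phi), phi += omega`` -- straight lines
    for omega = 0, circles of radius v/|omega| otherwise.  ``motion``
    optionally overrides each motor's (speed_v, omega).  Trailing
    bubbles are re-seeded every frame behind the current pose so the
    exhaust plume follows the motor; background bubbles stay put.

    ``boundary="wrap"`` folds positions into the field periodically (for
    long runs at high speed); ``"none"`` applies the bare update rule.

    Returns ``(frames, masks, trajectories)``; ``frames`` is empty when
    ``render=False`` (ground-truth-only runs are much cheaper).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    optics = optics or OpticsConfig()
    h, w = optics.shape
    rng = np.random.default_rng(seed)

    motors = [replace(m) for m in initial.motors]
    if motion is not None:
        if len(motion) != len(motors):
            raise ValueError("motion must give (speed_v, omega) per motor")
        for m, (v, om) in zip(motors, motion):
            m.speed_v, m.omega = float(v), float(om)
    background = [b for b in initial.bubbles if b.kind == "background"]

    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    trajectories = [GroundTruthTrajectory(i) for i in range(len(motors))]

    for f in range(n_frames):
        bubbles = list(background)
        for m in motors:
            bubbles.extend(_trailing_bubbles(m, rng))
        scene = Scene(frame_index=f, motors=[replace(m) for m in motors],
                      bubbles=bubbles)
        for i, m in enumerate(motors):
            trajectories[i].poses.append((f, replace(m)))
        masks.append(render_ground_truth(scene, optics, mask_mode))
        if render:
            frames.append(render_frame(scene, optics, rng=rng))
        motors = [_advance(m, boundary, w, h) for m in motors]

    return frames, masks, trajectories


# ----------------------------------------------------------- training data

def make_training_set(n_pairs: int, optics: Optional[OpticsConfig] = None,
                      mode: Literal["outline", "filled"] = "filled",
                      seed: int = 0,
                      n_motors_range: tuple[int, int] = (1, 4),
                      n_bubbles_range: tuple[int, int] = (1, 4)):
    """Draw ``n_pairs`` independent scenes and render aligned
    (frame, mask) pairs.

    Returns ``(frames, masks)`` as float32 (N, H, W) and uint8 (N, H, W)
    arrays.  Motor and background-bubble counts per scene are uniform on
    the given inclusive ranges.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    optics = optics or OpticsConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_pairs)
    frames = np.empty((n_pairs,) + optics.shape, dtype=np.float32)
    masks = np.empty((n_pairs,) + optics.shape, dtype=np.uint8)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        n_mot = int(rng.integers(n_motors_range[0], n_motors_range[1] + 1))
        n_bub = int(rng.integers(n_bubbles_range[0], n_bubbles_range[1] + 1))
        scene = sample_scene(optics, n_mot, n_bub,
                             seed=int(rng.integers(0, 2**31 - 1)))
        frames[i] = render_frame(scene, optics, rng=rng)
        masks[i] = render_ground_truth(scene, optics, mode)
    return frames, masks
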