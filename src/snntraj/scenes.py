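"""Synthetic ballistic throw scenes with exact ground truth.

Generates short grayscale videos of a ball thrown between two reception
columns, imaged by a fixed camera perpendicular to the trajectory plane.
Kinematics are closed-form ballistic motion in world coordinates, mapped
to pixels through a fixed ``pixel_pitch``; the renderer draws the ball as
a hard-edged disk, optionally animates thrower/receiver arm segments, and
adds Gaussian pixel noise.

Conventions
-----------
* Pixel coordinates: origin top-left, x rightward, y downward, 0-based.
  "Higher" ball positions therefore have *smaller* y.
* Direction angle: degrees clockwise from vertical-up, so 0 deg = upward,
  90 deg = horizontal rightward, 180 deg = downward, 270 deg = leftward.
  An ascending rightward throw sits near 45 deg, an ascending leftward
  throw near 315 deg, and the top of an arc near 90/270 deg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SceneConfig",
    "LaunchParams",
    "TrajectoryTruth",
    "FrameSequence",
    "TrajectoryItem",
    "simulate_trajectory",
    "render_frames",
    "make_dataset",
    "save_truth",
    "load_truth",
]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and noise of the synthetic recording setup.

    The defaults emulate a 128x120 px, 240 fps sensor watching a ~2.3 m
    throw that spans most of the sensor width.
    """

    width: int = 128
    height: int = 120
    fps: float = 240.0
    ball_radius: int = 3
    #: world meters per pixel; 2.3 m between reception columns 110 px apart
    pixel_pitch: float = 2.30 / 110.0
    gravity: float = 9.81
    background_level: float = 40.0
    ball_level: float = 200.0
    arm_enabled: bool = False
    #: persistent bobbing-bar distractor in the lower-center region
    distractor_enabled: bool = False
    noise_sigma: float = 0.0
    reception_x_left: int = 9
    reception_x_right: int = 119
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.ball_radius) <= 0 or self.fps <= 0:
            raise ValueError("width, height, fps and ball_radius must be positive")
        if not (0 <= self.reception_x_left < self.width
                and 0 <= self.reception_x_right < self.width):
            raise ValueError("reception columns must lie inside the frame")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class LaunchParams:
    """Initial conditions of a throw.

    ``x0, y0`` are pixels; ``v0`` is the launch speed in m/s; ``angle0``
    is the launch direction in degrees using the clockwise-from-up
    convention documented in the module header.
    """

    x0: float
    y0: float
    v0: float
    angle0: float


@dataclass
class TrajectoryTruth:
    """Per-frame ground truth for one throw (pixel units unless noted)."""

    times: np.ndarray          # s, strictly increasing with step 1/fps
    center: np.ndarray         # (n, 2) pixel (x, y) per frame
    velocity: np.ndarray       # (n, 2) pixel/s (vx, vy) per frame
    direction_angle: np.ndarray  # degrees in [0, 360)
    speed: np.ndarray          # pixel/s
    direction_label: str       # "left" | "right"
    reception_y: float | None  # pixel crossing height, None if no crossing
    launch_params: LaunchParams

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Duration of the clip in seconds (frame count / fps)."""
        dt = self.times[1] - self.times[0] if len(self.times) > 1 else 0.0
        return len(self.times) * dt


@dataclass
class FrameSequence:
    """A stack of grayscale frames (n, height, width) at a fixed rate."""

    frames: np.ndarray
    fps: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class TrajectoryItem:
    """One dataset element: rendered frames plus their ground truth."""

    truth: TrajectoryTruth
    frames: FrameSequence


def direction_angle_from_velocity(vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    """Angle in degrees, clockwise from vertical-up, of a pixel-space velocity.

    ``vy`` is the *downward* pixel velocity, so upward motion has vy < 0.
    """
    ang = np.degrees(np.arctan2(vx, -np.asarray(vy, dtype=float)))
    return np.mod(ang, 360.0)


def _world_velocity(v0: float, angle0: float) -> tuple[float, float]:
    """(vx_world rightward, vy_world upward) in m/s from speed + angle."""
    rad = np.radians(angle0)
    return v0 * np.sin(rad), v0 * np.cos(rad)


def simulate_trajectory(config: SceneConfig, launch: LaunchParams) -> TrajectoryTruth:
    """Closed-form ballistic kinematics sampled at the sensor frame rate.

    The trajectory is truncated at the first crossing of the reception
    column on the side the ball travels toward (left column for leftward
    throws, right column for rightward ones), or when the ball leaves the
    frame by more than its radius. ``reception_y`` is the exact crossing
    height solved from the closed form, not a frame sample.
    """
    if launch.v0 < 0:
        raise ValueError("launch speed must be non-negative")
    if not (0 <= launch.x0 < config.width and 0 <= launch.y0 < config.height):
        raise ValueError("launch position must lie inside the frame")

    pitch = config.pixel_pitch
    vxw, vyw = _world_velocity(launch.v0, launch.angle0)
    # pixel-space kinematics: x right, y down
    vx_px = vxw / pitch
    vy0_px = -vyw / pitch            # upward world velocity decreases pixel y
    g_px = config.gravity / pitch    # downward accel increases pixel y

    rightward = vx_px >= 0
    label = "right" if rightward else "left"
    x_target = config.reception_x_right if rightward else config.reception_x_left

    # exact reception-column crossing time (linear horizontal motion)
    t_cross: float | None = None
    if vx_px != 0:
        tc = (x_target - launch.x0) / vx_px
        if tc > 0:
            t_cross = tc

    # sample frames until crossing or frame exit
    dt = 1.0 / config.fps
    margin = config.ball_radius
    times, xs, ys = [], [], []
    k = 0
    max_frames = int(20.0 * config.fps)  # hard stop: 20 s of simulated time
    while k < max_frames:
        t = k * dt
        x = launch.x0 + vx_px * t
        y = launch.y0 + vy0_px * t + 0.5 * g_px * t * t
        out = (x < -margin or x >= config.width + margin
               or y < -margin or y >= config.height + margin)
        if out:
            break
        times.append(t)
        xs.append(x)
        ys.append(y)
        if t_cross is not None and t >= t_cross:
            break
        k += 1
    if not times:
        raise ValueError("trajectory never enters the field of view")

    times_a = np.asarray(times)
    center = np.column_stack([xs, ys])
    vy_px = vy0_px + g_px * times_a
    velocity = np.column_stack([np.full_like(times_a, vx_px), vy_px])
    speed = np.hypot(velocity[:, 0], velocity[:, 1])
    angle = direction_angle_from_velocity(velocity[:, 0], velocity[:, 1])

    reception_y: float | None = None
    if t_cross is not None and times_a[-1] >= t_cross:
        yc = launch.y0 + vy0_px * t_cross + 0.5 * g_px * t_cross**2
        if 0 <= yc < config.height:
            reception_y = float(yc)

    return TrajectoryTruth(
        times=times_a,
        center=center,
        velocity=velocity,
        direction_angle=angle,
        speed=speed,
        direction_label=label,
        reception_y=reception_y,
        launch_params=launch,
    )


def _draw_disk(frame: np.ndarray, cx: float, cy: float, r: float, level: float) -> None:
    """Rasterize a filled disk (x-cx)^2 + (y-cy)^2 <= r^2, no anti-aliasing."""
    h, w = frame.shape
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r))
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r))
    x0, x1 = max(x0, 0), min(x1, w - 1)
    y0, y1 = max(y0, 0), min(y1, h - 1)
    if x0 > x1 or y0 > y1:
        return
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    frame[y0:y1 + 1, x0:x1 + 1][mask] = level


def _draw_bar(frame: np.ndarray, x0: float, y0: float, x1: float, y1: float,
              half_width: float, level: float) -> None:
    """Rasterize a thick line segment (the 'arm')."""
    h, w = frame.shape
    n = max(int(np.hypot(x1 - x0, y1 - y0)) * 2, 2)
    for s in np.linspace(0.0, 1.0, n):
        _draw_disk(frame, x0 + s * (x1 - x0), y0 + s * (y1 - y0),
                   half_width, level)


def render_frames(truth: TrajectoryTruth, config: SceneConfig,
                  rng: np.random.Generator | None = None) -> FrameSequence:
    """Render the throw as a grayscale frame stack.

    The ball is a filled disk at each ground-truth center. When
    ``config.arm_enabled``, a thrower-arm segment pivots at a shoulder
    point below the launch position during the first ~0.15 s of the clip,
    providing independently moving non-ball structure. Gaussian noise with
    ``noise_sigma`` is added per pixel; output is clipped to [0, 255].
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = truth.n_frames
    frames = np.empty((n, config.height, config.width), dtype=np.float32)
    launch = truth.launch_params
    arm_frames = int(round(0.15 * config.fps))
    shoulder = (launch.x0, min(launch.y0 + 0.35 * config.height,
                               config.height - 1))
    arm_len = 0.3 * config.height
    sweep = np.radians(80.0)
    sign = 1.0 if truth.direction_label == "right" else -1.0

    for i in range(n):
        f = frames[i]
        f[:] = config.background_level
        if config.arm_enabled and i < arm_frames:
            # arm rotates from behind the throw toward the launch direction
            phase = i / max(arm_frames - 1, 1)
            theta = sign * (-sweep / 2 + sweep * phase)
            tip = (shoulder[0] + arm_len * np.sin(theta),
                   shoulder[1] - arm_len * np.cos(theta))
            _draw_bar(f, shoulder[0], shoulder[1], tip[0], tip[1],
                      half_width=1.5, level=0.7 * config.ball_level)
        if config.distractor_enabled:
            # horizontal bar bobbing vertically in the lower-center region,
            # independent of the ball and orthogonal to its motion in both
            # edge orientation and movement direction
            t = truth.times[i]
            y_bar = 0.82 * config.height + 0.06 * config.height * np.sin(
                2 * np.pi * t / 0.6)
            _draw_bar(f, 0.40 * config.width, y_bar,
                      0.60 * config.width, y_bar,
                      half_width=1.5, level=config.ball_level)
        cx, cy = truth.center[i]
        _draw_disk(f, cx, cy, config.ball_radius, config.ball_level)
        if config.noise_sigma > 0:
            f += rng.normal(0.0, config.noise_sigma, f.shape).astype(np.float32)
    np.clip(frames, 0.0, 255.0, out=frames)
    return FrameSequence(frames=frames, fps=config.fps)


@dataclass(frozen=True)
class LaunchRanges:
    """Sampling ranges for random throws (both directions, multiple speeds)."""

    speed_min: float = 3.0       # m/s
    speed_max: float = 6.0
    #: launch elevation from vertical toward the throw direction, degrees
    elev_min: float = 30.0
    elev_max: float = 60.0
    y0_frac_min: float = 0.55    # launch height as fraction of frame height
    y0_frac_max: float = 0.85


def sample_launch(config: SceneConfig, rng: np.random.Generator,
                  ranges: LaunchRanges | None = None,
                  direction: str | None = None) -> LaunchParams:
    """Draw one launch: side, speed and elevation from the configured ranges."""
    if ranges is None:
        ranges = LaunchRanges()
    if direction is None:
        direction = "right" if rng.random() < 0.5 else "left"
    v0 = rng.uniform(ranges.speed_min, ranges.speed_max)
    elev = rng.uniform(ranges.elev_min, ranges.elev_max)
    y0 = rng.uniform(ranges.y0_frac_min, ranges.y0_frac_max) * (config.height - 1)
    if direction == "right":
        x0 = config.reception_x_left + config.ball_radius + 1
        angle0 = elev
    else:
        x0 = config.reception_x_right - config.ball_radius - 1
        angle0 = 360.0 - elev
    return LaunchParams(x0=float(x0), y0=float(y0), v0=float(v0), angle0=float(angle0))


def make_dataset(n_trajectories: int, config: SceneConfig,
                 split_fraction: float = 0.70,
                 ranges: LaunchRanges | None = None,
                 render: bool = True,
                 ) -> tuple[list[TrajectoryItem], list[TrajectoryItem]]:
    """Generate a seeded train/test dataset of random throws.

    Launches alternate between valid draws until ``n_trajectories`` throws
    with an in-frame reception crossing are collected; the split is a
    seeded disjoint partition with ``round(n * split_fraction)`` training
    items (297 throws at 0.70 give the 208/89 partition).
    """
    if n_trajectories < 2:
        raise ValueError("need at least 2 trajectories to populate both splits")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    n_train = int(round(n_trajectories * split_fraction))
    if n_train == 0 or n_train == n_trajectories:
        raise ValueError("split leaves one side empty")

    rng = np.random.default_rng(config.seed)
    items: list[TrajectoryItem] = []
    attempts = 0
    while len(items) < n_trajectories:
        attempts += 1
        if attempts > 50 * n_trajectories:
            raise RuntimeError("launch ranges rarely produce valid throws")
        direction = "right" if len(items) % 2 == 0 else "left"
        launch = sample_launch(config, rng, ranges, direction=direction)
        try:
            truth = simulate_trajectory(config, launch)
        except ValueError:
            continue
        if truth.reception_y is None or truth.n_frames < 8:
            continue
        frames = render_frames(truth, config, rng=rng) if render else None
        items.append(TrajectoryItem(truth=truth, frames=frames))

    perm = rng.permutation(n_trajectories)
    train = [items[i] for i in perm[:n_train]]
    test = [items[i] for i in perm[n_train:]]
    return train, test


# ---------------------------------------------------------------------------
# plain-text persistence: per-frame CSV + JSON sidecar

def save_truth(truth: TrajectoryTruth, csv_path: str | Path) -> None:
    """Write per-frame truth as CSV plus a JSON sidecar with launch params."""
    csv_path = Path(csv_path)
    df = pd.DataFrame({
        "t": truth.times,
        "x": truth.center[:, 0],
        "y": truth.center[:, 1],
        "vx": truth.velocity[:, 0],
        "vy": truth.velocity[:, 1],
        "angle": truth.direction_angle,
        "speed": truth.speed,
    })
    df.to_csv(csv_path, index=False)
    side = {
        "launch_params": asdict(truth.launch_params),
        "direction_label": truth.direction_label,
        "reception_y": truth.reception_y,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def load_truth(csv_path: str | Path) -> TrajectoryTruth:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    return TrajectoryTruth(
        times=df["t"].to_numpy(),
        center=df[["x", "y"]].to_numpy(),
        velocity=df[["vx", "vy"]].to_numpy(),
        direction_angle=df["angle"].to_numpy(),
        speed=df["speed"].to_numpy(),
        direction_label=side["direction_label"],
        reception_y=side["reception_y"],
        launch_params=LaunchParams(**side["launch_params"]),
    )
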