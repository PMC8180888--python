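"""Software emulation of a frame-based event camera.

The processing chain mirrors a global-shutter sensor with on-board
filtering: for every frame F >= 1 the inter-frame difference is filtered
with a center-surround difference-of-Gaussians (DoG) kernel, responses
above a magnitude threshold become ON/OFF events (sign of the filtered
response), and each frame's suprathreshold magnitudes are converted to
spike latencies spread across the inter-frame interval — the strongest
response fires first, the weakest lands at the next frame time:

    dt_rel = (1 - m) / fps,    t = F / fps + dt_rel,

with m the response magnitude min-max normalized within the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .scenes import FrameSequence

__all__ = [
    "FrontendConfig",
    "EventStream",
    "dog_kernel",
    "frontend_filter",
    "latency_encode",
    "encode_sequence",
    "auto_threshold",
    "save_events_csv",
    "load_events_csv",
]

ON, OFF = 1, 0


@dataclass(frozen=True)
class FrontendConfig:
    """DoG filter and thresholding parameters of the camera emulation."""

    dog_sigma_center: float = 1.0
    dog_sigma_surround: float = 2.0
    dog_kernel_size: int = 7
    threshold: float = 1.0
    fps: float = 240.0

    def __post_init__(self) -> None:
        if not (0 < self.dog_sigma_center < self.dog_sigma_surround):
            raise ValueError("need 0 < sigma_center < sigma_surround")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.dog_kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")


@dataclass
class EventStream:
    """Time-sorted address-event stream.

    ``t`` seconds, ``x``/``y`` pixel coordinates, ``polarity`` 1=ON, 0=OFF.
    Ties in ``t`` are stored in raster order (ascending y, then x), the
    stable ordering the simulator relies on.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    polarity: np.ndarray
    sensor_shape: tuple[int, int]   # (width, height)
    fps: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.polarity = np.asarray(self.polarity, dtype=np.int64)
        if np.any(np.diff(self.t) < 0):
            raise ValueError("event times must be non-decreasing")
        w, h = self.sensor_shape
        if len(self.x) and (self.x.min() < 0 or self.x.max() >= w
                            or self.y.min() < 0 or self.y.max() >= h):
            raise ValueError("event coordinates outside the sensor frame")

    def __len__(self) -> int:
        return len(self.t)

    def until(self, t_max: float) -> "EventStream":
        """Events with t <= t_max (visibility cutoffs)."""
        keep = self.t <= t_max
        return EventStream(self.t[keep], self.x[keep], self.y[keep],
                           self.polarity[keep], self.sensor_shape, self.fps)


def dog_kernel(config: FrontendConfig) -> np.ndarray:
    """Zero-mean center-surround kernel: unit-mass center minus surround."""
    k = config.dog_kernel_size
    r = k // 2
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = xx * xx + yy * yy
    center = np.exp(-d2 / (2 * config.dog_sigma_center**2))
    surround = np.exp(-d2 / (2 * config.dog_sigma_surround**2))
    center /= center.sum()
    surround /= surround.sum()
    return center - surround


def frontend_filter(frames: FrameSequence, config: FrontendConfig
                    ) -> list[dict[str, np.ndarray]]:
    """Suprathreshold DoG responses to the inter-frame difference.

    Returns one record per frame F >= 1 with the responding pixel
    coordinates, polarity (sign of the response) and magnitude. A
    single-frame input yields an empty list.
    """
    stack = np.asarray(frames.frames, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frames must be a (n, height, width) stack")
    out: list[dict[str, np.ndarray]] = []
    if stack.shape[0] < 2:
        return out
    kernel = dog_kernel(config)
    for f in range(1, stack.shape[0]):
        diff = stack[f] - stack[f - 1]
        resp = ndimage.convolve(diff, kernel, mode="constant", cval=0.0)
        yy, xx = np.nonzero(np.abs(resp) > config.threshold)
        vals = resp[yy, xx]
        out.append({
            "frame": f,
            "x": xx,
            "y": yy,
            "polarity": (vals > 0).astype(np.int64),
            "magnitude": np.abs(vals),
        })
    return out


def latency_encode(response: dict[str, np.ndarray], config: FrontendConfig,
                   sensor_shape: tuple[int, int]) -> EventStream:
    """Intensity-to-latency conversion of one frame's responses.

    Magnitudes are min-max normalized within the frame; the largest
    magnitude fires at the frame time (dt = 0) and the smallest exactly
    one frame period later. Equal magnitudes (including a frame with a
    single responding pixel) fire at dt = 0 and tie-break in raster
    order.
    """
    mag = np.asarray(response["magnitude"], dtype=float)
    f = int(response["frame"])
    if len(mag) == 0:
        empty = np.empty(0)
        return EventStream(empty, empty, empty, empty, sensor_shape, config.fps)
    lo, hi = mag.min(), mag.max()
    m = np.ones_like(mag) if hi == lo else (mag - lo) / (hi - lo)
    dt = (1.0 - m) / config.fps
    t = f / config.fps + dt
    order = np.lexsort((response["x"], response["y"], t))
    return EventStream(t[order], response["x"][order], response["y"][order],
                       response["polarity"][order], sensor_shape, config.fps)


def encode_sequence(frames: FrameSequence, config: FrontendConfig) -> EventStream:
    """Full camera emulation: filter every frame pair and merge the spikes.

    The result is globally time-sorted with raster-order tie-breaks and is
    deterministic for identical inputs.
    """
    h, w = frames.shape
    sensor_shape = (w, h)
    responses = frontend_filter(frames, config)
    parts = [latency_encode(r, config, sensor_shape) for r in responses
             if len(r["magnitude"])]
    if not parts:
        e = np.empty(0)
        return EventStream(e, e, e, e, sensor_shape, config.fps)
    t = np.concatenate([p.t for p in parts])
    x = np.concatenate([p.x for p in parts])
    y = np.concatenate([p.y for p in parts])
    pol = np.concatenate([p.polarity for p in parts])
    order = np.lexsort((x, y, t))
    return EventStream(t[order], x[order], y[order], pol[order],
                       sensor_shape, config.fps)


def auto_threshold(frames: FrameSequence, config: FrontendConfig,
                   target_fraction: float = 0.003) -> float:
    """Pick a threshold so ~``target_fraction`` of pixels respond per frame.

    Emulates the manual sensitivity adjustment done when recording: high
    enough to suppress noise, low enough to keep motion. Returns a new
    threshold value (the config is not modified).
    """
    stack = np.asarray(frames.frames, dtype=float)
    if stack.shape[0] < 2:
        raise ValueError("need at least two frames to tune the threshold")
    kernel = dog_kernel(config)
    mags = []
    for f in range(1, stack.shape[0]):
        diff = stack[f] - stack[f - 1]
        mags.append(np.abs(ndimage.convolve(diff, kernel, mode="constant")))
    allmag = np.concatenate([m.ravel() for m in mags])
    thr = float(np.quantile(allmag, 1.0 - target_fraction))
    return max(thr, 1e-9)


def tuned_config(frames: FrameSequence, config: FrontendConfig,
                 target_fraction: float = 0.003) -> FrontendConfig:
    """Copy of ``config`` with the threshold auto-tuned on ``frames``."""
    return replace(config, threshold=auto_threshold(frames, config, target_fraction))


# ---------------------------------------------------------------------------
# plain-text event I/O

def save_events_csv(stream: EventStream, path: str | Path) -> None:
    """CSV with header ``t,x,y,polarity`` (t seconds, polarity 1=ON/0=OFF)."""
    pd.DataFrame({"t": stream.t, "x": stream.x, "y": stream.y,
                  "polarity": stream.polarity}).to_csv(path, index=False)


def load_events_csv(path: str | Path, sensor_shape: tuple[int, int],
                    fps: float) -> EventStream:
    df = pd.read_csv(path)
    return EventStream(df["t"].to_numpy(), df["x"].to_numpy(),
                       df["y"].to_numpy(), df["polarity"].to_numpy(),
                       sensor_shape, fps)
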