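"""Post-hoc characterization of trained filters.

Three unsupervised selectivity analyses, all based on output spikes and
frame-level ground truth (direction angle, speed, ball center), matched
to each spike by nearest frame:

* direction tuning — per-1-degree-bin spike counts normalized by how
  often each direction occurred in the stimulus set, so the curve is
  invariant to the presented direction distribution;
* speed selectivity — the ball speeds at a filter's spikes compared
  against a direction-matched random draw from the pooled ground truth,
  which controls for the direction-speed correlation of ballistic
  motion; decided by a two-sample KS statistic against a permutation
  null;
* motion tracking — the mean distance between spike positions and the
  ball center mapped into the layer's retinotopic coordinates; filters
  below a distance threshold are "ball coding".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import LayerSpikes
from .scenes import TrajectoryTruth

__all__ = [
    "TuningCurve",
    "SpeedProfile",
    "TrackingProfile",
    "spike_frame_lookup",
    "direction_tuning",
    "direction_selectivity_index",
    "speed_selectivity",
    "ball_distance",
    "ks_2sample",
]

N_BINS = 360


@dataclass
class TuningCurve:
    """Occurrence-normalized direction tuning of one filter.

    ``theta_f`` has one bin per degree, normalized to unit maximum;
    ``theta_c`` is the preferred direction (peak after 5-degree boxcar
    smoothing, ties resolved by circular mean). ``empty`` flags filters
    with no spikes.
    """

    theta_f: np.ndarray
    theta_c: float
    n_spikes: int
    empty: bool = False


@dataclass
class SpeedProfile:
    """Spike-triggered speeds vs a direction-matched random control."""

    speeds_at_spikes: np.ndarray
    control_speeds: np.ndarray
    ks_statistic: float
    p_value: float
    selective: bool
    insufficient: bool = False


@dataclass
class TrackingProfile:
    """Mean spike-to-ball distance of one filter."""

    d_n: float
    ball_coding: bool
    undefined: bool = False


def spike_frame_lookup(spike_t: np.ndarray, truth: TrajectoryTruth) -> np.ndarray:
    """Index of the ground-truth frame nearest to each spike time."""
    dt = truth.times[1] - truth.times[0] if len(truth.times) > 1 else 1.0
    idx = np.rint((np.asarray(spike_t) - truth.times[0]) / dt).astype(int)
    return np.clip(idx, 0, len(truth.times) - 1)


def _collect(spikes_per_traj: list[LayerSpikes],
             truths: list[TrajectoryTruth], filt: int):
    """Per-spike (direction, speed, frame-index, traj-index) for one filter."""
    dirs, speeds, frames, trajs, xs, ys = [], [], [], [], [], []
    for ti, (rec, truth) in enumerate(zip(spikes_per_traj, truths)):
        sel = rec.f == filt
        if not sel.any():
            continue
        idx = spike_frame_lookup(rec.t[sel], truth)
        dirs.append(truth.direction_angle[idx])
        speeds.append(truth.speed[idx])
        frames.append(idx)
        trajs.append(np.full(sel.sum(), ti))
        xs.append(rec.x[sel])
        ys.append(rec.y[sel])
    if not dirs:
        z = np.empty(0)
        return z, z, z.astype(int), z.astype(int), z, z
    return (np.concatenate(dirs), np.concatenate(speeds),
            np.concatenate(frames), np.concatenate(trajs),
            np.concatenate(xs), np.concatenate(ys))


def _occurrences(truths: list[TrajectoryTruth]) -> np.ndarray:
    """Frames per 1-degree direction bin over all presented throws."""
    occ = np.zeros(N_BINS)
    for truth in truths:
        bins = np.rint(truth.direction_angle).astype(int) % N_BINS
        np.add.at(occ, bins, 1)
    return occ


def _smooth_circular(v: np.ndarray, window: int) -> np.ndarray:
    k = np.ones(window) / window
    return np.convolve(np.concatenate([v[-(window // 2):], v, v[:window // 2]]),
                       k, mode="valid")


def direction_tuning(spikes_per_traj: list[LayerSpikes],
                     truths: list[TrajectoryTruth], filt: int,
                     smooth_deg: int = 5) -> TuningCurve:
    """Occurrence-normalized, unit-peak direction tuning curve.

    Spike counts per 1-degree bin are divided by the number of frames in
    which that direction occurred, making the curve independent of the
    marginal direction distribution of the presented throws.
    """
    dirs, _, _, _, _, _ = _collect(spikes_per_traj, truths, filt)
    if len(dirs) == 0:
        return TuningCurve(theta_f=np.zeros(N_BINS), theta_c=np.nan,
                           n_spikes=0, empty=True)
    counts = np.zeros(N_BINS)
    np.add.at(counts, np.rint(dirs).astype(int) % N_BINS, 1)
    occ = _occurrences(truths)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(occ > 0, counts / occ, 0.0)
    if theta.max() > 0:
        theta = theta / theta.max()
    sm = _smooth_circular(theta, smooth_deg)
    peak = sm.max()
    tied = np.flatnonzero(np.isclose(sm, peak))
    if len(tied) == 1:
        theta_c = float(tied[0])
    else:  # circular mean of tied bins
        ang = np.radians(tied.astype(float))
        theta_c = float(np.degrees(np.arctan2(np.sin(ang).mean(),
                                              np.cos(ang).mean())) % 360)
    return TuningCurve(theta_f=theta, theta_c=theta_c, n_spikes=len(dirs))


def direction_selectivity_index(curve: TuningCurve,
                                smooth_deg: int = 5) -> float:
    """DSI = (R_pref - R_opp) / (R_pref + R_opp) from the tuning curve."""
    if curve.empty:
        return 0.0
    sm = _smooth_circular(curve.theta_f, smooth_deg)
    pref = int(round(curve.theta_c)) % N_BINS
    opp = (pref + 180) % N_BINS
    rp, ro = sm[pref], sm[opp]
    if rp + ro == 0:
        return 0.0
    return float((rp - ro) / (rp + ro))


def ks_2sample(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov distance (no ties correction)."""
    a = np.sort(a)
    b = np.sort(b)
    allv = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, allv, side="right") / len(a)
    cdf_b = np.searchsorted(b, allv, side="right") / len(b)
    return float(np.abs(cdf_a - cdf_b).max())


def speed_selectivity(spikes_per_traj: list[LayerSpikes],
                      truths: list[TrajectoryTruth], filt: int,
                      curve: TuningCurve | None = None,
                      n_control: int | None = None,
                      n_permutations: int = 1000,
                      alpha: float = 0.05,
                      seed: int = 0,
                      min_spikes: int = 10) -> SpeedProfile:
    """Speed selectivity against a direction-matched control.

    The control draws directions from the filter's tuning curve, then
    samples pooled ground-truth speeds conditioned on those direction
    bins (with replacement), so the direction-speed correlation of
    ballistic flight cannot masquerade as speed tuning. Selectivity is
    declared when the KS distance between spike-triggered and control
    speeds exceeds the (1 - alpha) quantile of a label-permutation null.
    """
    rng = np.random.default_rng(seed)
    _, speeds, _, _, _, _ = _collect(spikes_per_traj, truths, filt)
    if len(speeds) < min_spikes:
        return SpeedProfile(speeds_at_spikes=speeds,
                            control_speeds=np.empty(0),
                            ks_statistic=np.nan, p_value=np.nan,
                            selective=False, insufficient=True)
    if curve is None:
        curve = direction_tuning(spikes_per_traj, truths, filt)
    if n_control is None:
        n_control = 10 * len(speeds)

    # pooled ground truth grouped by direction bin
    pool_dir, pool_speed = [], []
    for truth in truths:
        pool_dir.append(np.rint(truth.direction_angle).astype(int) % N_BINS)
        pool_speed.append(truth.speed)
    pool_dir = np.concatenate(pool_dir)
    pool_speed = np.concatenate(pool_speed)
    by_bin: dict[int, np.ndarray] = {
        int(b): pool_speed[pool_dir == b] for b in np.unique(pool_dir)}

    # sample control directions from the filter's expected spike-count
    # profile: tuning (theta_f) times how often each direction occurred.
    # theta_f alone would mismatch the spike direction mixture whenever
    # occupancy is non-uniform and misflag null filters.
    occupied = np.array(sorted(by_bin))
    occ_counts = np.array([len(by_bin[int(b)]) for b in occupied], dtype=float)
    w = curve.theta_f[occupied] * occ_counts
    if w.sum() == 0:
        w = np.ones_like(w)
    w = w / w.sum()
    ctrl_bins = rng.choice(occupied, size=n_control, p=w)
    control = np.array([by_bin[int(b)][rng.integers(len(by_bin[int(b)]))]
                        for b in ctrl_bins])

    ks = ks_2sample(speeds, control)
    pooled = np.concatenate([speeds, control])
    n = len(speeds)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(pooled))
        null[i] = ks_2sample(pooled[perm[:n]], pooled[perm[n:]])
    p_value = float((np.sum(null >= ks) + 1) / (n_permutations + 1))
    thresh = float(np.quantile(null, 1.0 - alpha))
    return SpeedProfile(speeds_at_spikes=speeds, control_speeds=control,
                        ks_statistic=ks, p_value=p_value,
                        selective=bool(ks > thresh))


def ball_distance(spikes_per_traj: list[LayerSpikes],
                  truths: list[TrajectoryTruth], filt: int,
                  layer_index: int,
                  threshold: float | None = None,
                  sensor_shape: tuple[int, int] = (128, 120)) -> TrackingProfile:
    """Mean Euclidean spike-to-ball distance in map coordinates.

    The ball center moves into layer k's retinotopic frame by
    subtracting 2 px per 5x5 valid convolution stage. The default
    ball-coding threshold is 6 px at the native 128x120 resolution,
    scaled by the geometric mean of the width/height ratios for other
    sensor sizes; the comparison is strict (d_n exactly at threshold is
    not ball coding).
    """
    if threshold is None:
        w, h = sensor_shape
        threshold = 6.0 * float(np.sqrt((w / 128.0) * (h / 120.0)))
    offset = 2.0 * (layer_index + 1)
    dists = []
    for rec, truth in zip(spikes_per_traj, truths):
        sel = rec.f == filt
        if not sel.any():
            continue
        idx = spike_frame_lookup(rec.t[sel], truth)
        cx = truth.center[idx, 0] - offset
        cy = truth.center[idx, 1] - offset
        dists.append(np.hypot(rec.x[sel] - cx, rec.y[sel] - cy))
    if not dists:
        return TrackingProfile(d_n=np.nan, ball_coding=False, undefined=True)
    d_n = float(np.concatenate(dists).mean())
    return TrackingProfile(d_n=d_n, ball_coding=bool(d_n < threshold))
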