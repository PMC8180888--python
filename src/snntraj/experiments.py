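"""Reproducible scaled-down experiments on synthetic scenes.

Each function freezes one study design — stimulus geometry, network
size, presentation counts — and exposes only the seed (plus a few
ablation switches), so the same conditions can be re-run from tests,
scripts or a shell. The designs are desk-scale versions of the full
128x120 / 60-80-100-filter pipeline; sizes were chosen so each
experiment runs in minutes on one core while keeping the published
dynamical constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .scenes import (SceneConfig, LaunchParams, LaunchRanges,
                     simulate_trajectory, render_frames, make_dataset)
from .frontend import FrontendConfig, encode_sequence, tuned_config
from .network import (Network, DelayConfig, published_layer_params, run_network,
                      train_network)
from .readout import fit_readout, evaluate_visibility
from .analysis import (direction_tuning, direction_selectivity_index,
                       ball_distance, speed_selectivity, spike_frame_lookup)

__all__ = [
    "moving_dot_experiment",
    "end_to_end_experiment",
    "tracking_experiment",
    "kernel_decorrelation",
    "speed_test_calibration",
    "mean_pairwise_cosine",
]


# ---------------------------------------------------------------------------
# direction selectivity on moving dots

@dataclass
class DotResult:
    dsi: np.ndarray            # per-filter DSI
    theta_c: np.ndarray        # per-filter preferred direction (deg)
    counts: np.ndarray         # (n_filters, 2) spikes for right/left tests
    both_directions: bool
    network: Network
    spikes_per_traj: list
    truths: list


def moving_dot_experiment(seed: int, delays_on: bool = True,
                          n_pres: int = 100, n_test: int = 60,
                          n_filters: int = 8, size: int = 48,
                          fps: float = 30.0, u_thresh_base: float = 16.0,
                          network: Network | None = None,
                          train: bool = True) -> DotResult:
    """Train a 1-layer net on dots sweeping left vs right; measure tuning.

    A 2 px dot crosses a ``size`` x ``size`` field at one pixel per frame,
    ``n_pres`` presentations per direction at random heights. The frame
    rate (30 fps) makes the delay lines (1 and 2 frame periods) long
    against the 10 ms membrane constant, and the raised threshold puts
    layer 1 in a coincidence-detection regime. ``delays_on=False``
    zeroes the delay lines for the paired control (same seed).
    """
    cfg = SceneConfig(width=size, height=size, fps=fps, ball_radius=2,
                      pixel_pitch=1.0, gravity=0.0, reception_x_left=1,
                      reception_x_right=size - 2, seed=seed)
    v0 = 1.0 * fps    # 1 px/frame
    sample = simulate_trajectory(cfg, LaunchParams(3, size // 2, v0, 90))
    fc = tuned_config(render_frames(sample, cfg), FrontendConfig(fps=fps),
                      target_fraction=0.002)
    rng = np.random.default_rng(seed)

    def clip(direction: str, y0: float):
        x0 = 3.0 if direction == "right" else size - 4.0
        ang = 90.0 if direction == "right" else 270.0
        truth = simulate_trajectory(cfg, LaunchParams(x0, y0, v0, ang))
        return encode_sequence(render_frames(truth, cfg), fc), truth

    if network is None:
        delays = (0.0, 1.0 / fps, 2.0 / fps) if delays_on else (0.0, 0.0, 0.0)
        lp = replace(published_layer_params()[0], n_filters=n_filters,
                     u_thresh_base=u_thresh_base)
        network = Network((size, size), [lp], DelayConfig(delays), seed=seed)
        if train:
            streams = [clip("right" if i % 2 == 0 else "left",
                            rng.uniform(6, size - 6))[0]
                       for i in range(2 * n_pres)]
            train_network(streams, network, epochs_per_layer=1)
    else:
        if train:
            raise ValueError("pass either a trained network or train=True")

    counts = np.zeros((n_filters, 2))
    spikes_per_traj, truths = [], []
    for i in range(n_test):
        d = "right" if i % 2 == 0 else "left"
        ev, truth = clip(d, rng.uniform(6, size - 6))
        rec = run_network(ev, network, n_layers=1)[0]
        spikes_per_traj.append(rec)
        truths.append(truth)
        np.add.at(counts[:, 0 if d == "right" else 1], rec.f, 1)

    dsi = np.zeros(n_filters)
    theta_c = np.full(n_filters, np.nan)
    for f in range(n_filters):
        curve = direction_tuning(spikes_per_traj, truths, f)
        dsi[f] = direction_selectivity_index(curve)
        theta_c[f] = curve.theta_c
    both = bool((counts[:, 0] > counts[:, 1]).any()
                and (counts[:, 1] > counts[:, 0]).any())
    return DotResult(dsi=dsi, theta_c=theta_c, counts=counts,
                     both_directions=both, network=network,
                     spikes_per_traj=spikes_per_traj, truths=truths)


# ---------------------------------------------------------------------------
# end-to-end trajectory prediction

@dataclass
class EndToEndResult:
    percentages: tuple
    mean_ae: np.ndarray
    sd_ae: np.ndarray
    direction_errors: np.ndarray
    baseline_mean_ae: float
    n_test: int
    network: Network
    model: object
    test_spikes: list
    test_truths: list


def _scaled_scene(seed: int) -> tuple[SceneConfig, LaunchRanges]:
    cfg = SceneConfig(width=64, height=48, fps=60.0, ball_radius=2,
                      pixel_pitch=2.30 / 53.0, gravity=9.81,
                      reception_x_left=5, reception_x_right=58, seed=seed)
    ranges = LaunchRanges(speed_min=3.0, speed_max=6.0,
                          elev_min=30.0, elev_max=60.0,
                          y0_frac_min=0.55, y0_frac_max=0.85)
    return cfg, ranges


def end_to_end_experiment(seed: int, n_train: int = 60, n_test: int = 20,
                          n_filters: tuple[int, int, int] = (16, 20, 24),
                          trained: bool = True,
                          percentages: tuple = (15, 30, 45, 60, 75, 90),
                          ) -> EndToEndResult:
    """Full pipeline on a 64x48 synthetic throw set.

    Generates ``n_train`` + ``n_test`` ballistic throws, encodes them,
    trains the 3-layer network layer-by-layer (skipped when
    ``trained=False``, leaving the seeded random kernels), fits the
    per-filter quadratic readout on training-set output spikes, and
    sweeps prediction visibility on the test set.
    """
    cfg, ranges = _scaled_scene(seed)
    train_items, test_items = make_dataset(n_train + n_test, cfg,
                                           split_fraction=n_train / (n_train + n_test),
                                           ranges=ranges)
    fps = cfg.fps
    fc = tuned_config(train_items[0].frames, FrontendConfig(fps=fps),
                      target_fraction=0.003)
    enc = lambda item: encode_sequence(item.frames, fc)

    delays = DelayConfig((0.0, 1.0 / fps, 2.0 / fps))
    layers = published_layer_params(n_filters)
    net = Network((cfg.width, cfg.height), layers, delays, seed=seed)

    train_streams = [enc(it) for it in train_items]
    if trained:
        train_network(train_streams, net, epochs_per_layer=1)

    # output-layer spikes on the training set for the readout fit
    train_spikes = [run_network(s, net)[-1] for s in train_streams]
    train_truths = [it.truth for it in train_items]
    model = fit_readout(train_spikes, train_truths,
                        n_filters=layers[-1].n_filters, height=cfg.height)

    test_spikes = [run_network(enc(it), net)[-1] for it in test_items]
    test_truths = [it.truth for it in test_items]
    ev = evaluate_visibility(test_spikes, test_truths, model,
                             percentages=percentages)
    return EndToEndResult(percentages=ev["percentages"],
                          mean_ae=ev["mean_ae"], sd_ae=ev["sd_ae"],
                          direction_errors=ev["direction_errors"],
                          baseline_mean_ae=ev["baseline_mean_ae"],
                          n_test=ev["n_trajectories"], network=net,
                          model=model, test_spikes=test_spikes,
                          test_truths=test_truths)


# ---------------------------------------------------------------------------
# unsupervised tracking with a distractor

@dataclass
class TrackingResult:
    d_n: np.ndarray
    ball_coding: np.ndarray
    frac_near_ball: float      # ball-coding filters' spikes within 2 radii
    threshold: float


def tracking_experiment(seed: int, n_train: int = 40, n_test: int = 15,
                        n_filters: int = 16) -> TrackingResult:
    """Ball + moving-arm scenes; split filters by mean ball distance.

    Scenes contain the thrown ball plus a bar oscillating in the lower
    half of the frame, independent of the throw. After unsupervised
    training of one layer, each filter's mean spike-to-ball distance
    decides whether it codes for the ball; the fraction of ball-coding
    filters' spikes within two ball radii of the center is also
    reported. The ball-coding threshold is ``ball_radius + 3`` px: event
    spikes sit on the moving edge, so even a perfectly ball-locked
    filter has a distance floor of about one radius plus the filter
    support.
    """
    cfg, ranges = _scaled_scene(seed)
    cfg = replace(cfg, distractor_enabled=True, ball_radius=3)
    train_items, test_items = make_dataset(
        n_train + n_test, cfg, split_fraction=n_train / (n_train + n_test),
        ranges=ranges)
    fc = tuned_config(train_items[0].frames, FrontendConfig(fps=cfg.fps),
                      target_fraction=0.003)
    lp = replace(published_layer_params()[0], n_filters=n_filters)
    net = Network((cfg.width, cfg.height), [lp],
                  DelayConfig((0.0, 1.0 / cfg.fps, 2.0 / cfg.fps)), seed=seed)
    train_network([encode_sequence(it.frames, fc) for it in train_items], net,
                  epochs_per_layer=1)

    spikes, truths = [], []
    for it in test_items:
        spikes.append(run_network(encode_sequence(it.frames, fc), net,
                                  n_layers=1)[0])
        truths.append(it.truth)

    w, h = cfg.width, cfg.height
    threshold = cfg.ball_radius + 3.0
    d_n = np.full(n_filters, np.nan)
    coding = np.zeros(n_filters, dtype=bool)
    near, total = 0, 0
    for f in range(n_filters):
        prof = ball_distance(spikes, truths, f, layer_index=0,
                             threshold=threshold, sensor_shape=(w, h))
        d_n[f] = prof.d_n
        coding[f] = prof.ball_coding
    for rec, truth in zip(spikes, truths):
        sel = np.isin(rec.f, np.flatnonzero(coding))
        if not sel.any():
            continue
        idx = spike_frame_lookup(rec.t[sel], truth)
        cx = truth.center[idx, 0] - 2.0
        cy = truth.center[idx, 1] - 2.0
        d = np.hypot(rec.x[sel] - cx, rec.y[sel] - cy)
        near += int((d <= 2 * cfg.ball_radius).sum())
        total += len(d)
    frac = near / total if total else np.nan
    return TrackingResult(d_n=d_n, ball_coding=coding, frac_near_ball=frac,
                          threshold=threshold)


# ---------------------------------------------------------------------------
# lateral inhibition decorrelates kernels

def mean_pairwise_cosine(kernel: np.ndarray) -> float:
    """Mean pairwise cosine similarity between flattened filters."""
    flat = kernel.reshape(kernel.shape[0], -1)
    norm = flat / np.linalg.norm(flat, axis=1, keepdims=True)
    sim = norm @ norm.T
    iu = np.triu_indices(len(flat), k=1)
    return float(sim[iu].mean())


def kernel_decorrelation(seed: int, n_pres: int = 60) -> dict:
    """Mean pairwise kernel similarity with vs without lateral inhibition.

    Trains the moving-dot layer twice from identical seeds, once with
    the published inhibition strength and once with f_inst = 0.
    """
    out = {}
    table_f_inst = published_layer_params()[0].f_inst
    for label, f_inst in (("inhibition_on", table_f_inst),
                          ("inhibition_off", 0.0)):
        cfg = SceneConfig(width=48, height=48, fps=30.0, ball_radius=2,
                          pixel_pitch=1.0, gravity=0.0, reception_x_left=1,
                          reception_x_right=46, seed=seed)
        sample = simulate_trajectory(cfg, LaunchParams(3, 24, 30.0, 90))
        fc = tuned_config(render_frames(sample, cfg),
                          FrontendConfig(fps=30.0), target_fraction=0.002)
        rng = np.random.default_rng(seed)
        lp = replace(published_layer_params()[0], n_filters=8,
                     u_thresh_base=16.0, f_inst=f_inst)
        net = Network((48, 48), [lp],
                      DelayConfig((0.0, 1 / 30.0, 2 / 30.0)), seed=seed)
        streams = []
        for i in range(2 * n_pres):
            d = "right" if i % 2 == 0 else "left"
            x0 = 3.0 if d == "right" else 44.0
            ang = 90.0 if d == "right" else 270.0
            truth = simulate_trajectory(
                cfg, LaunchParams(x0, rng.uniform(6, 42), 30.0, ang))
            streams.append(encode_sequence(render_frames(truth, cfg), fc))
        train_network(streams, net, epochs_per_layer=1)
        out[label] = mean_pairwise_cosine(net.kernels[0])
    return out


# ---------------------------------------------------------------------------
# calibration of the speed-selectivity permutation test

def speed_test_calibration(seed: int, n_repeats: int = 200,
                           n_spikes: int = 80,
                           n_permutations: int = 500) -> dict:
    """Type-I rate of the permutation test on direction-matched nulls.

    Null filters draw spike frames by direction preference only (a von
    Mises tuning bump), so their speed distribution follows the
    direction-conditioned pool exactly; a well-calibrated test should
    flag ~alpha of them. A constructed filter restricted to the top
    decile of direction-matched speeds must be flagged selective.
    """
    from .network import LayerSpikes

    cfg, ranges = _scaled_scene(seed)
    train_items, test_items = make_dataset(40, cfg, split_fraction=0.5,
                                           ranges=ranges, render=False)
    truths = [it.truth for it in train_items + test_items]
    rng = np.random.default_rng(seed)

    # frame pool across trajectories
    frames = [(ti, fi) for ti, tr in enumerate(truths)
              for fi in range(tr.n_frames)]
    dirs = np.array([truths[ti].direction_angle[fi] for ti, fi in frames])
    speeds = np.array([truths[ti].speed[fi] for ti, fi in frames])

    def spikes_from_frames(chosen: np.ndarray) -> list:
        per = [[] for _ in truths]
        for j in chosen:
            ti, fi = frames[j]
            per[ti].append(truths[ti].times[fi])
        recs = []
        for ti, ts in enumerate(per):
            ts = np.sort(np.array(ts))
            z = np.zeros(len(ts))
            recs.append(LayerSpikes(t=ts, f=z.astype(np.int64),
                                    y=z.astype(np.int64), x=z.astype(np.int64),
                                    u=z, layer=0))
        return recs

    def vm_weights(mu_deg: float, kappa: float = 8.0) -> np.ndarray:
        return np.exp(kappa * np.cos(np.radians(dirs - mu_deg)))

    false_pos = 0
    for r in range(n_repeats):
        mu = rng.uniform(0, 360)
        w = vm_weights(mu)
        w /= w.sum()
        chosen = rng.choice(len(frames), size=n_spikes, replace=True, p=w)
        recs = spikes_from_frames(chosen)
        prof = speed_selectivity(recs, truths, 0,
                                 n_permutations=n_permutations,
                                 seed=int(rng.integers(2**31)))
        if prof.selective:
            false_pos += 1
    type1 = false_pos / n_repeats

    # constructed effect: top decile of direction-matched speeds
    mu = 45.0
    w = vm_weights(mu)
    w /= w.sum()
    cand = rng.choice(len(frames), size=20 * n_spikes, replace=True, p=w)
    cut = np.quantile(speeds[cand], 0.9)
    top = cand[speeds[cand] >= cut][:n_spikes]
    prof = speed_selectivity(spikes_from_frames(top), truths, 0,
                             n_permutations=n_permutations,
                             seed=int(rng.integers(2**31)))
    return {"type1_rate": type1, "constructed_selective": bool(prof.selective),
            "constructed_ks": prof.ks_statistic}
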