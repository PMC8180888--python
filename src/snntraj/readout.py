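"""Supervised end-point readout on output-layer spikes.

Each output filter n gets its own second-degree polynomial regression

    Y_pred,n = a00 + a10 x + a01 y + a20 x^2 + a02 y^2 + a11 x y

mapping the map position (x, y) of a spiking neuron to the ball's
reception height (the vertical pixel position where the ball crosses the
reception column on the side it travels toward). The per-filter training
RMSE measures each regression's reliability; at decode time every spike
adds a kernel to a score array over candidate heights, centered on its
filter's prediction, weighted by 1/RMSE and widened by RMSE, so reliable
filters dominate. The final prediction is the argmax of the leaky score.
Left/right direction is decoded separately by majority vote over the
spiking filters' training-set direction labels — the quadratic fit never
sees it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import LayerSpikes
from .scenes import TrajectoryTruth

__all__ = [
    "ReadoutModel",
    "ScoreState",
    "fit_readout",
    "predict_y",
    "update_score",
    "decode_prediction",
    "predict_direction",
    "evaluate_visibility",
]

N_COEFFS = 6
MIN_SPIKES = 6  # one per coefficient


def _design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.column_stack([np.ones_like(x), x, y, x * x, y * y, x * y])


@dataclass
class ReadoutModel:
    """Per-filter quadratic coefficients plus reliability and direction.

    ``usable`` marks filters with at least six training spikes; others
    are excluded from scoring. ``training_mean_y`` is the mean reception
    height over the training set — the naive constant predictor used as
    prior and baseline.
    """

    coeffs: np.ndarray           # (n_filters, 6)
    rmse: np.ndarray             # (n_filters,) pixels
    direction_label: np.ndarray  # (n_filters,) "left"/"right"/""
    usable: np.ndarray           # (n_filters,) bool
    training_mean_y: float
    height: int                  # frame height, pixels (score-array range)

    @property
    def n_filters(self) -> int:
        return len(self.rmse)


def fit_readout(spikes_per_traj: list[LayerSpikes],
                truths: list[TrajectoryTruth],
                n_filters: int, height: int) -> ReadoutModel:
    """Least-squares fit of the per-filter quadratic readout.

    ``spikes_per_traj`` holds the output-layer spikes of each training
    trajectory; the regression target for every spike is its
    trajectory's reception height. Filters with fewer than six training
    spikes are flagged unusable. Raises if no filter is usable.
    """
    if len(spikes_per_traj) != len(truths):
        raise ValueError("one spike record per training trajectory required")
    rows_x = [[] for _ in range(n_filters)]
    rows_y = [[] for _ in range(n_filters)]
    targets = [[] for _ in range(n_filters)]
    labels = [[] for _ in range(n_filters)]
    ys_all = []
    for rec, truth in zip(spikes_per_traj, truths):
        if truth.reception_y is None:
            continue
        ys_all.append(truth.reception_y)
        for i in range(len(rec)):
            f = int(rec.f[i])
            rows_x[f].append(float(rec.x[i]))
            rows_y[f].append(float(rec.y[i]))
            targets[f].append(float(truth.reception_y))
            labels[f].append(truth.direction_label)
    if not ys_all:
        raise ValueError("no training trajectory has a reception crossing")
    mean_y = float(np.mean(ys_all))

    coeffs = np.zeros((n_filters, N_COEFFS))
    rmse = np.full(n_filters, np.inf)
    direction = np.array([""] * n_filters, dtype=object)
    usable = np.zeros(n_filters, dtype=bool)
    for f in range(n_filters):
        n = len(targets[f])
        if n < MIN_SPIKES:
            continue
        A = _design(np.array(rows_x[f]), np.array(rows_y[f]))
        b = np.array(targets[f])
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        resid = A @ sol - b
        coeffs[f] = sol
        rmse[f] = float(np.sqrt(np.mean(resid**2)))
        n_right = sum(1 for lab in labels[f] if lab == "right")
        direction[f] = "right" if n_right * 2 >= n else "left"
        usable[f] = True
    if not usable.any():
        raise ValueError("no filter has enough training spikes for a fit")
    return ReadoutModel(coeffs=coeffs, rmse=rmse, direction_label=direction,
                        usable=usable, training_mean_y=mean_y, height=height)


def predict_y(model: ReadoutModel, filt: int, x: float, y: float) -> float:
    """Evaluate filter ``filt``'s quadratic at map position (x, y)."""
    if not model.usable[filt]:
        raise ValueError(f"filter {filt} is unusable (too few training spikes)")
    a00, a10, a01, a20, a02, a11 = model.coeffs[filt]
    return float(a00 + a10 * x + a01 * y + a20 * x * x + a02 * y * y
                 + a11 * x * y)


@dataclass
class ScoreState:
    """Leaky score over candidate reception heights (1 px bins).

    ``tau`` is the exponential leak time constant in seconds;
    ``None`` disables the leak. ``kernel`` selects the bump shape added
    per spike: "gaussian" (default) or "triangular".
    """

    height: int
    tau: float | None = 0.5
    kernel: str = "gaussian"
    score: np.ndarray = field(default=None)  # type: ignore[assignment]
    last_update: float = 0.0

    def __post_init__(self) -> None:
        if self.score is None:
            self.score = np.zeros(self.height)
        self.grid = np.arange(self.height, dtype=float)

    def reset(self) -> None:
        self.score[:] = 0.0
        self.last_update = 0.0


def update_score(state: ScoreState, t: float, filt: int, x: float, y: float,
                 model: ReadoutModel, min_sigma: float = 1.0,
                 eps: float = 1e-6) -> ScoreState:
    """Add one spike's prediction kernel to the leaky score array.

    The kernel is centered on the filter's predicted height with peak
    height 1/RMSE and width max(RMSE, ``min_sigma``) pixels, so filters
    with low training error contribute sharp, tall bumps.
    """
    if state.tau is not None and t > state.last_update:
        state.score *= np.exp(-(t - state.last_update) / state.tau)
    state.last_update = max(state.last_update, t)
    yp = predict_y(model, filt, x, y)
    r = model.rmse[filt]
    sigma = max(r, min_sigma)
    peak = 1.0 / max(r, eps)
    d = state.grid - yp
    if state.kernel == "triangular":
        bump = peak * np.clip(1.0 - np.abs(d) / (2.0 * sigma), 0.0, None)
    else:
        bump = peak * np.exp(-0.5 * (d / sigma) ** 2)
    state.score += bump
    return state


def decode_prediction(state: ScoreState, model: ReadoutModel) -> float:
    """Argmax of the score; falls back to the training mean when empty."""
    if not np.any(state.score > 0):
        return model.training_mean_y
    return float(np.argmax(state.score))


def predict_direction(filters_so_far: np.ndarray, model: ReadoutModel
                      ) -> str | None:
    """Majority vote of direction labels over the observed spikes.

    Ties resolve to the most recent spike's label; with no spikes the
    decoder abstains (returns None).
    """
    votes = [model.direction_label[int(f)] for f in filters_so_far
             if model.usable[int(f)]]
    if not votes:
        return None
    n_right = votes.count("right")
    n_left = votes.count("left")
    if n_right > n_left:
        return "right"
    if n_left > n_right:
        return "left"
    return votes[-1]


def evaluate_visibility(spikes_per_traj: list[LayerSpikes],
                        truths: list[TrajectoryTruth],
                        model: ReadoutModel,
                        percentages: tuple[float, ...] = (15, 30, 45, 60, 75, 90),
                        score_tau: float | None = 0.5,
                        ) -> dict:
    """Absolute end-point error as a function of trajectory visibility.

    For each test trajectory and each percentage p, only output spikes
    up to p% of the clip duration enter the score (reset per
    trajectory); the prediction is decoded at the cutoff and compared to
    the true reception height (AE, pixels). Direction errors count
    decoded-direction mismatches (abstentions count as errors). The
    naive baseline always predicts the training-set mean height.

    Returns a dict with per-percentage mean AE, SD AE, direction error
    counts, the per-trajectory AE matrix, and the baseline mean AE.
    """
    percentages = tuple(percentages)
    n_traj = len(truths)
    ae = np.full((n_traj, len(percentages)), np.nan)
    dir_err = np.zeros(len(percentages), dtype=int)
    base_ae = []
    for i, (rec, truth) in enumerate(zip(spikes_per_traj, truths)):
        if truth.reception_y is None:
            continue
        base_ae.append(abs(model.training_mean_y - truth.reception_y))
        order = np.argsort(rec.t, kind="stable")
        for j, p in enumerate(percentages):
            t_cut = truth.duration * p / 100.0
            state = ScoreState(height=model.height, tau=score_tau)
            seen = []
            for k in order:
                if rec.t[k] > t_cut:
                    break
                f = int(rec.f[k])
                if not model.usable[f]:
                    continue
                update_score(state, float(rec.t[k]), f,
                             float(rec.x[k]), float(rec.y[k]), model)
                seen.append(f)
            pred = decode_prediction(state, model)
            ae[i, j] = abs(pred - truth.reception_y)
            d = predict_direction(np.array(seen), model)
            if d != truth.direction_label:
                dir_err[j] += 1
    valid = ~np.isnan(ae[:, 0])
    return {
        "percentages": percentages,
        "mean_ae": np.nanmean(ae, axis=0),
        "sd_ae": np.nanstd(ae, axis=0, ddof=1),
        "direction_errors": dir_err,
        "ae": ae,
        "n_trajectories": int(valid.sum()),
        "baseline_mean_ae": float(np.mean(base_ae)) if base_ae else np.nan,
    }
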