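"""Quadratic readout: fitting, scoring, decoding, visibility sweeps."""

import numpy as np
import pytest

from snntraj.network import LayerSpikes
from snntraj.scenes import LaunchParams, TrajectoryTruth
from snntraj.readout import (ReadoutModel, ScoreState, fit_readout, predict_y,
                             update_score, decode_prediction,
                             predict_direction, evaluate_visibility)


def spikes(t, f, x, y, layer=2):
    t = np.asarray(t, float)
    return LayerSpikes(t=t, f=np.asarray(f), y=np.asarray(y),
                       x=np.asarray(x), u=np.ones_like(t), layer=layer)


def truth(reception_y, direction="right", n=20, fps=60.0):
    times = np.arange(n) / fps
    return TrajectoryTruth(
        times=times, center=np.column_stack([np.linspace(5, 40, n),
                                             np.linspace(30, 20, n)]),
        velocity=np.tile([120.0, -30.0], (n, 1)),
        direction_angle=np.full(n, 80.0 if direction == "right" else 280.0),
        speed=np.full(n, 123.0), direction_label=direction,
        reception_y=reception_y, launch_params=LaunchParams(5, 30, 4, 45))


def manual_model(coeffs, rmse=1.0, height=48, prior=20.0, label="right"):
    c = np.atleast_2d(np.asarray(coeffs, float))
    n = len(c)
    return ReadoutModel(coeffs=c, rmse=np.full(n, rmse),
                        direction_label=np.array([label] * n, dtype=object),
                        usable=np.ones(n, bool), training_mean_y=prior,
                        height=height)


class TestFit:
    def test_exact_linear_surface_recovered(self):
        rng = np.random.default_rng(0)
        xs = rng.uniform(0, 30, 40)
        ys = rng.uniform(0, 30, 40)
        # one trajectory per spike so each target is exact: Y = 2 + 0.5 x
        recs = [spikes([0.0], [0], [x], [y]) for x, y in zip(xs, ys)]
        truths = [truth(2.0 + 0.5 * x) for x in xs]
        model = fit_readout(recs, truths, n_filters=1, height=48)
        assert np.allclose(model.coeffs[0], [2.0, 0.5, 0, 0, 0, 0], atol=1e-6)
        assert model.rmse[0] < 1e-9

    def test_constant_target_gives_intercept_only(self):
        rng = np.random.default_rng(1)
        xs = rng.uniform(0, 30, 40)
        ys = rng.uniform(0, 30, 40)
        recs = [spikes([0.0], [0], [x], [y]) for x, y in zip(xs, ys)]
        truths = [truth(17.0) for _ in xs]
        model = fit_readout(recs, truths, n_filters=1, height=48)
        assert model.coeffs[0][0] == pytest.approx(17.0, abs=1e-6)
        assert np.allclose(model.coeffs[0][1:], 0.0, atol=1e-6)

    def test_underdetermined_filter_flagged_unusable(self):
        # a filter with >= 6 spikes is fitted; one below the coefficient
        # count is excluded
        recs = [spikes([0] * 9, [0] * 6 + [1] * 3,
                       list(range(6)) + [1, 2, 3],
                       [0, 1, 2, 0, 1, 2, 1, 2, 3])]
        model = fit_readout(recs, [truth(10.0)], n_filters=2, height=48)
        assert model.usable[0] and not model.usable[1]

    def test_no_usable_filter_raises(self):
        recs = [spikes([0.0], [0], [1], [1])]
        with pytest.raises(ValueError):
            fit_readout(recs, [truth(10.0)], n_filters=1, height=48)

    def test_direction_label_majority(self):
        recs = [spikes([0] * 4, [0] * 4, range(4), range(4)),
                spikes([0] * 3, [0] * 3, range(3), range(3))]
        truths = [truth(10.0, "right"), truth(12.0, "left")]
        model = fit_readout(recs, truths, n_filters=1, height=48)
        assert model.direction_label[0] == "right"


class TestPredict:
    def test_zero_coefficients_give_zero(self):
        m = manual_model([[0, 0, 0, 0, 0, 0]])
        assert predict_y(m, 0, 5.0, 9.0) == 0.0

    def test_constant_naive_predictor_value(self):
        # the published naive predictor: a00 = 68.2 px, everything else 0
        m = manual_model([[68.2, 0, 0, 0, 0, 0]], height=120)
        assert predict_y(m, 0, 3.0, 4.0) == pytest.approx(68.2)
        assert predict_y(m, 0, 90.0, 110.0) == pytest.approx(68.2)

    def test_full_quadratic_evaluation(self):
        m = manual_model([[1, 2, 3, 4, 5, 6]])
        # 1 + 2*2 + 3*3 + 4*4 + 5*9 + 6*6 = 111
        assert predict_y(m, 0, 2.0, 3.0) == pytest.approx(111.0)

    def test_unusable_filter_rejected(self):
        m = manual_model([[1, 0, 0, 0, 0, 0]])
        m.usable[0] = False
        with pytest.raises(ValueError):
            predict_y(m, 0, 1.0, 1.0)


class TestScore:
    def test_flat_score_decodes_to_prior(self):
        m = manual_model([[30, 0, 0, 0, 0, 0]], prior=21.5)
        state = ScoreState(height=48)
        assert decode_prediction(state, m) == pytest.approx(21.5)

    def test_single_spike_argmax_at_prediction(self):
        m = manual_model([[30.0, 0, 0, 0, 0, 0]])
        state = ScoreState(height=48)
        update_score(state, 0.0, 0, 1.0, 1.0, m)
        assert decode_prediction(state, m) == 30

    def test_reliable_filter_dominates(self):
        # predictions 10 and 40 px with RMSE 1 vs 10: argmax lands on 10
        m = ReadoutModel(
            coeffs=np.array([[10.0, 0, 0, 0, 0, 0], [40.0, 0, 0, 0, 0, 0]]),
            rmse=np.array([1.0, 10.0]),
            direction_label=np.array(["right", "right"], dtype=object),
            usable=np.ones(2, bool), training_mean_y=25.0, height=48)
        state = ScoreState(height=48)
        update_score(state, 0.0, 0, 0.0, 0.0, m)
        update_score(state, 0.0, 1, 0.0, 0.0, m)
        assert abs(decode_prediction(state, m) - 10.0) <= 1.0

    def test_accumulation_preserves_argmax(self):
        m = manual_model([[22.0, 0, 0, 0, 0, 0]])
        state = ScoreState(height=48)
        for k in range(20):
            update_score(state, k * 0.01, 0, 2.0, 3.0, m)
        assert decode_prediction(state, m) == 22

    def test_decode_invariant_to_uniform_scaling(self):
        m = manual_model([[30.0, 0, 0, 0, 0, 0]])
        state = ScoreState(height=48)
        update_score(state, 0.0, 0, 1.0, 1.0, m)
        before = decode_prediction(state, m)
        state.score *= 7.3
        assert decode_prediction(state, m) == before

    def test_score_leaks_toward_zero_without_spikes(self):
        m = manual_model([[30.0, 0, 0, 0, 0, 0]])
        state = ScoreState(height=48, tau=0.1)
        update_score(state, 0.0, 0, 1.0, 1.0, m)
        peak = state.score.max()
        update_score(state, 1.0, 0, 1.0, 1.0, m)  # 10 tau later + new bump
        # the old contribution decayed by e^-10
        assert state.score.max() < 2 * peak
        assert np.all(state.score >= 0)


class TestDirection:
    def test_unanimous_vote(self):
        m = manual_model([[0] * 6, [0] * 6], label="right")
        assert predict_direction(np.array([0, 1, 0]), m) == "right"

    def test_majority_seven_to_three(self):
        m = ReadoutModel(
            coeffs=np.zeros((2, 6)), rmse=np.ones(2),
            direction_label=np.array(["right", "left"], dtype=object),
            usable=np.ones(2, bool), training_mean_y=0.0, height=48)
        votes = np.array([0] * 7 + [1] * 3)
        assert predict_direction(votes, m) == "right"

    def test_tie_resolves_to_most_recent(self):
        m = ReadoutModel(
            coeffs=np.zeros((2, 6)), rmse=np.ones(2),
            direction_label=np.array(["right", "left"], dtype=object),
            usable=np.ones(2, bool), training_mean_y=0.0, height=48)
        assert predict_direction(np.array([0, 1]), m) == "left"
        assert predict_direction(np.array([1, 0]), m) == "right"

    def test_no_spikes_abstains(self):
        m = manual_model([[0] * 6])
        assert predict_direction(np.array([]), m) is None


class TestVisibility:
    def test_perfect_readout_gives_zero_error(self):
        # filter 0 predicts exactly the spike's y coordinate; spikes are
        # injected at y = reception height from the very start
        m = manual_model([[0, 0, 1, 0, 0, 0]], rmse=0.5)
        truths = [truth(30.0), truth(12.0)]
        recs = [spikes([0.001, 0.01, 0.2], [0] * 3, [1] * 3, [30] * 3),
                spikes([0.001, 0.01, 0.2], [0] * 3, [1] * 3, [12] * 3)]
        ev = evaluate_visibility(recs, truths, m)
        assert np.allclose(ev["mean_ae"], 0.0)

    def test_silent_tail_makes_late_percentages_equal(self):
        m = manual_model([[0, 0, 1, 0, 0, 0]], rmse=0.5)
        t = truth(30.0, n=100)             # duration 100/60 s
        # all spikes happen in the first half of the clip
        rec = spikes([0.01, 0.2, 0.5], [0] * 3, [1] * 3, [25, 28, 30])
        ev = evaluate_visibility([rec], [t], m, percentages=(90, 100))
        assert ev["mean_ae"][0] == ev["mean_ae"][1]

    def test_baseline_is_training_mean_error(self):
        m = manual_model([[0, 0, 1, 0, 0, 0]], prior=20.0)
        truths = [truth(30.0), truth(14.0)]
        recs = [spikes([0.01], [0], [1], [30]), spikes([0.01], [0], [1], [14])]
        ev = evaluate_visibility(recs, truths, m)
        assert ev["baseline_mean_ae"] == pytest.approx((10.0 + 6.0) / 2)
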