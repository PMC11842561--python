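"""Tests for behavioural metrics, activity-change analyses, decoders and
state-space fits."""

import numpy as np
import pytest

from reachrnn.analysis import (activity_change, classify_units,
                               compare_models, decoder_backtest,
                               fb_ff_unit_correlation, find_peak_times,
                               fit_dual_rate, fit_lag_decoder,
                               fit_single_rate, fit_velocity_decoder,
                               learning_vs_error_correlation,
                               simulate_dual_rate, simulate_single_rate,
                               smooth_error_curve, takeoff_angle,
                               takeoff_error, DEFAULT_WINDOWS)
from reachrnn.core import TrialResult
from reachrnn.plasticity import PlasticityConfig, SessionPhase, run_adaptation
from reachrnn.tasks import TrialSpec

DT = 0.01
T = 300


def _fake_result(p_cursor, trial, y=None):
    p_cursor = np.asarray(p_cursor, float)
    return TrialResult(trial=trial, seed=0, takeoff_angle_deg=np.nan,
                       takeoff_error_deg=np.nan, endpoint_error_cm=np.nan,
                       p_cursor=p_cursor, p_star=np.zeros_like(p_cursor),
                       epsilon=np.zeros_like(p_cursor),
                       v=np.zeros_like(p_cursor), y=y)


def _ramp_trial(direction_deg, target_deg, go_time=1.0):
    """Cursor at rest until go, then moving at fixed heading with a
    triangular speed profile peaking mid-movement."""
    trial = TrialSpec(p_start=[0, 0],
                      p_end=5 * np.array([np.cos(np.deg2rad(target_deg)),
                                          np.sin(np.deg2rad(target_deg))]),
                      go_time=go_time)
    go = int(go_time / DT)
    speed = np.zeros(T)
    up = np.linspace(0, 1, 50)
    speed[go:go + 50] = up
    speed[go + 50:go + 100] = up[::-1]
    heading = np.deg2rad(direction_deg)
    vel = np.outer(speed, [np.cos(heading), np.sin(heading)])
    p = np.cumsum(vel * DT, axis=0)
    return _fake_result(p, trial)


class TestTakeoff:
    def test_straight_reach_along_x(self):
        res = _ramp_trial(0.0, 0.0)
        assert takeoff_angle(res) == pytest.approx(0.0, abs=1e-9)
        assert takeoff_error(res) == pytest.approx(0.0, abs=1e-9)

    def test_error_wraps_to_half_circle(self):
        res = _ramp_trial(-170.0, 170.0)
        assert takeoff_error(res) == pytest.approx(20.0, abs=1e-9)

    def test_no_movement_raises(self):
        trial = TrialSpec(p_start=[0, 0], p_end=[5, 0], go_time=1.0)
        res = _fake_result(np.zeros((T, 2)), trial)
        with pytest.raises(ValueError, match="take-off"):
            takeoff_angle(res)


class TestSmoothing:
    def test_constant_preserved_exactly(self):
        x = np.full(200, 3.7)
        np.testing.assert_allclose(smooth_error_curve(x), x, rtol=1e-12)

    def test_impulse_gives_gaussian_kernel(self):
        x = np.zeros(401)
        x[200] = 1.0
        s = smooth_error_curve(x, sd_trials=10)
        assert np.argmax(s) == 200
        assert s[210] / s[200] == pytest.approx(np.exp(-0.5), rel=1e-3)

    def test_sum_preserved_under_reflection(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=120)
        assert smooth_error_curve(x).sum() == pytest.approx(x.sum(),
                                                            abs=1e-9)


class TestLearningCorrelation:
    def test_proportional_learning_gives_r_one(self):
        errors = 30.0 * 0.9 ** np.arange(100)   # e(n+1) = 0.9 e(n)
        r, p = learning_vs_error_correlation(errors)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_errors_uncorrelated(self):
        rng = np.random.default_rng(1)
        rs = []
        for k in range(30):
            errors = rng.permutation(30.0 * 0.9 ** np.arange(200))
            # shuffling removes the error -> next-trial-learning link up
            # to the arithmetic coupling of adjacent |e| differences
            r, _ = learning_vs_error_correlation(errors)
            rs.append(r)
        # mean correlation of shuffled sequences sits well below the
        # r = 1 of ordered learning
        assert np.mean(rs) < 0.8


class TestActivityChange:
    def _probe(self, ys, go_time=1.45):
        trial = TrialSpec(p_start=[0, 0], p_end=[5, 0], go_time=go_time)
        return [_fake_result(np.zeros((T, 2)), trial, y=y) for y in ys]

    def test_identical_probes_give_zero_trace(self):
        rng = np.random.default_rng(2)
        ys = [rng.random((T, 10)) for _ in range(4)]
        tr = activity_change(self._probe(ys), self._probe(ys))
        assert np.all(tr.trace == 0)

    def test_planted_peaks_recovered_exactly(self):
        go = 145
        t = np.arange(T) * DT
        ys_a, ys_b, ys_c = [], [], []
        for _ in range(3):
            base = np.zeros((T, 5))
            fb = base + np.exp(-(t[:, None] - (1.45 + 0.8)) ** 2 / 0.01)
            ff = base + np.exp(-(t[:, None] - (1.45 + 0.5)) ** 2 / 0.01)
            ys_a.append(base)
            ys_b.append(fb)
            ys_c.append(ff)
        tr_fb = activity_change(self._probe(ys_a), self._probe(ys_b))
        tr_ff = activity_change(self._probe(ys_a), self._probe(ys_c))
        ff_t, fb_t = find_peak_times([tr_ff], [tr_fb])
        assert ff_t == pytest.approx(0.5, abs=DT / 2)
        assert fb_t == pytest.approx(0.8, abs=DT / 2)

    def test_linear_in_single_unit_change(self):
        rng = np.random.default_rng(3)
        N = 8
        ys1 = [rng.random((T, N)) for _ in range(2)]
        ys2 = [y.copy() for y in ys1]
        extra = 0.5
        for y in ys2:
            y[:, 3] += extra
        tr = activity_change(self._probe(ys1), self._probe(ys2))
        np.testing.assert_allclose(tr.trace, extra / N, rtol=1e-12)

    def test_mismatched_probe_sets_rejected(self):
        ys = [np.zeros((T, 3))]
        with pytest.raises(ValueError):
            activity_change(self._probe(ys), self._probe(ys * 2))


class TestClassification:
    @pytest.fixture(scope="class")
    def null_session(self, trained_net):
        """No perturbation, no plasticity: every unit is a true null."""
        phases = [SessionPhase("baseline", 20),
                  SessionPhase("perturbation", 60, rotation_deg=0.0,
                               plasticity_on=False)]
        return run_adaptation(trained_net, phases, seed=17,
                              snapshot_every=0,
                              record_windows=DEFAULT_WINDOWS)

    def test_false_positive_rate_calibrated(self, trained_net,
                                            null_session):
        cls = classify_units(trained_net, null_session, seed=5)
        # 95th-percentile null => ~5% positives per type
        for key in ("any_feedback", "any_learning"):
            assert cls["fractions"][key] < 0.16

    def test_injected_late_change_classified_feedback(self, trained_net,
                                                      null_session):
        import copy
        log = copy.copy(null_session)
        log.window_activity = {k: v.copy()
                               for k, v in null_session.window_activity.items()}
        log.window_activity["fb"][:, 7] += 1.0   # unit 7, late window only
        cls = classify_units(trained_net, log, seed=5)
        assert cls["labels"][7] == "feedback"

    def test_unit_correlation_trivial_cases(self):
        x = np.random.default_rng(4).random(60)
        cls = {"labels": np.array(["both"] * 60), "fb_change": x,
               "ff_change": x}
        r, p, n = fb_ff_unit_correlation(cls)
        assert r == pytest.approx(1.0)
        assert n == 60
        rng = np.random.default_rng(5)
        cls["ff_change"] = rng.permutation(x)
        r2, _, _ = fb_ff_unit_correlation(cls)
        assert abs(r2) < 0.4


class TestDecoder:
    def test_lag_zero_linear_map_recovered(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(2, 20))
        ys = [rng.random((100, 20)) for _ in range(6)]
        vs = [y @ A.T for y in ys]
        dec = fit_lag_decoder(ys[:3], vs[:3], np.arange(20), 0)
        pred = dec.predict(ys[4])
        np.testing.assert_allclose(pred, vs[4], atol=1e-5)

    def test_shuffled_targets_give_zero_accuracy(self):
        rng = np.random.default_rng(7)
        trial = TrialSpec(p_start=[0, 0], p_end=[5, 0], go_time=1.0)
        trials = []
        for _ in range(40):
            y = rng.random((T, 15))
            v = rng.normal(size=(T, 2))   # unrelated to y
            res = _fake_result(np.zeros((T, 2)), trial, y=y)
            res.v = v
            trials.append(res)
        acc = fit_velocity_decoder(trials, unit_subset_size=15,
                                   lags_s=[0.0], n_train=20)
        assert acc.r2.iloc[0] < 0.2

    def test_backtest_flat_without_learning(self, trained_net):
        phases = [SessionPhase("perturbation", 60, rotation_deg=30.0,
                               plasticity_on=True)]
        log = run_adaptation(trained_net, phases,
                             PlasticityConfig(eta=0.0), seed=19,
                             snapshot_every=0,
                             record_activity_phases=("perturbation",))
        bt = decoder_backtest(log, n_train_last=20, seed=3)
        early = bt.r2[:20].mean()
        late = bt.r2[-20:].mean()
        assert abs(early - late) < 0.05


class TestStateSpace:
    TRUE = dict(A_f=0.92, A_s=0.996, B_f=0.03, B_s=0.004)

    def test_dual_rate_parameter_recovery(self):
        """Mean fitted parameters over replicate synthetic sessions are
        within 10% of the generating values, and the F-test prefers the
        dual-rate model."""
        fits = []
        for seed in range(5):
            x, e = simulate_dual_rate(n=600, noise_sd=0.01, seed=seed,
                                      **self.TRUE)
            fd = fit_dual_rate(x, e)
            fs = fit_single_rate(x, e)
            assert compare_models(fs, fd).preferred_model == "dual"
            fits.append(fd.params)
        for key, true in self.TRUE.items():
            mean = np.mean([f[key] for f in fits])
            assert mean == pytest.approx(true, rel=0.10), key

    def test_single_rate_ground_truth_not_overfit(self):
        prefer_dual = 0
        for seed in range(5):
            x, e = simulate_single_rate(A=0.98, B=0.02, n=600,
                                        noise_sd=0.01, seed=seed)
            fs = fit_single_rate(x, e)
            fd = fit_dual_rate(x, e)
            assert fs.params["A"] == pytest.approx(0.98, abs=0.02)
            prefer_dual += compare_models(fs, fd).preferred_model == "dual"
        assert prefer_dual <= 1

    def test_dual_constraints_and_nesting(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.5, 0.2, 80)
        e = rng.normal(0.3, 0.2, 80)
        fs, fd = fit_single_rate(x, e), fit_dual_rate(x, e)
        assert fd.params["A_f"] < fd.params["A_s"]
        assert fd.params["B_f"] > fd.params["B_s"]
        assert fd.rss <= fs.rss + 1e-6

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            fit_single_rate([0.1, 0.2], [1.0, 0.9])
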