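"""Behavioural metrics and population-activity analyses.

Covers: take-off angles and trial-by-trial learning statistics;
absolute activity-change traces between behavioural epochs (baseline /
perturbation onset / late adaptation) and their feedforward (~0.5 s
after go) and feedback (~0.8 s after go) peaks; null-calibrated
classification of units into feedback- / learning-responsive classes;
linear velocity decoders and their back-testing across adaptation; and
single- vs dual-rate state-space fits of the learning time course.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter1d
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score

from .core import NetworkParams, TrialResult, _takeoff
from .plasticity import AdaptationLog, replay_trial

__all__ = [
    "takeoff_angle",
    "takeoff_error",
    "smooth_error_curve",
    "learning_vs_error_correlation",
    "ActivityChangeTrace",
    "activity_change",
    "find_peak_times",
    "fb_ff_ratio",
    "classify_units",
    "fb_ff_unit_correlation",
    "fit_lag_decoder",
    "fit_velocity_decoder",
    "decoder_backtest",
    "StateSpaceFit",
    "FTestResult",
    "prepare_adaptation_series",
    "fit_single_rate",
    "fit_dual_rate",
    "compare_models",
    "simulate_dual_rate",
    "simulate_single_rate",
]


# --------------------------------------------------------------------------
# behavioural metrics

def takeoff_angle(result: TrialResult) -> float:
    """Initial reach direction (deg): cursor displacement between the go
    cue and the moment of peak cursor speed."""
    ang, _ = _takeoff(result.p_cursor, result.trial,
                      result.trial.duration / len(result.p_cursor))
    if np.isnan(ang):
        raise ValueError("no movement: take-off angle undefined")
    return ang


def takeoff_error(result: TrialResult) -> float:
    """Signed angular deviation of the take-off direction from the target
    direction, wrapped to (-180, 180]."""
    _, err = _takeoff(result.p_cursor, result.trial,
                      result.trial.duration / len(result.p_cursor))
    if np.isnan(err):
        raise ValueError("no movement: take-off error undefined")
    return err


def smooth_error_curve(errors: Sequence[float],
                       sd_trials: float = 10.0) -> np.ndarray:
    """Gaussian smoothing (s.d. in trials) with reflecting boundaries."""
    return gaussian_filter1d(np.asarray(errors, dtype=float), sd_trials,
                             mode="reflect")


def learning_vs_error_correlation(errors_or_log) -> tuple:
    """Pearson correlation between |error(n)| and the next-trial error
    reduction |error(n)| - |error(n+1)| over perturbation-phase trials.

    Accepts an :class:`AdaptationLog` or a raw error sequence.  The
    p-value is the joint-normality (t-distribution) null of pearsonr.
    """
    if isinstance(errors_or_log, AdaptationLog):
        errors = errors_or_log.errors("perturbation")
    else:
        errors = np.asarray(errors_or_log, dtype=float)
    ae = np.abs(errors)
    keep = np.isfinite(ae[:-1]) & np.isfinite(ae[1:])
    r, p = stats.pearsonr(ae[:-1][keep], (ae[:-1] - ae[1:])[keep])
    return float(r), float(p)


# --------------------------------------------------------------------------
# epoch activity changes

@dataclass
class ActivityChangeTrace:
    """Per-step mean |activity difference| between two matched epochs."""
    trace: np.ndarray      # (T,), >= 0
    dt: float
    go_step: int
    label: str = ""

    def peak_time_s(self) -> float:
        """Latency (s after go) of the trace maximum at or after the go
        cue."""
        seg = self.trace[self.go_step:]
        return float(int(np.argmax(seg)) * self.dt)

    def value_at(self, t_after_go_s: float) -> float:
        idx = self.go_step + int(round(t_after_go_s / self.dt))
        return float(self.trace[idx])


def activity_change(probe_1: Sequence[TrialResult],
                    probe_2: Sequence[TrialResult],
                    label: str = "") -> ActivityChangeTrace:
    """Mean over units and matched trial pairs of |y1(t) - y2(t)|.

    The probes must be matched one-to-one (same specs and seeds) and run
    at a common go time so steps are aligned to the go cue.
    """
    if len(probe_1) != len(probe_2):
        raise ValueError("probe sets must be matched one-to-one")
    diffs = [np.abs(r1.y - r2.y) for r1, r2 in zip(probe_1, probe_2)]
    trace = np.mean([d.mean(axis=1) for d in diffs], axis=0)
    tr = probe_1[0].trial
    dt = tr.duration / len(probe_1[0].p_cursor)
    return ActivityChangeTrace(trace=trace, dt=dt,
                               go_step=int(round(tr.go_time / dt)),
                               label=label)


def find_peak_times(traces_learning: Sequence[ActivityChangeTrace],
                    traces_feedback: Sequence[ActivityChangeTrace]) -> tuple:
    """(ff_time, fb_time) in s after go, from across-network averages.

    The feedforward (learning) peak is the maximum of the average
    late-vs-early-adaptation (C vs B) trace; the feedback peak is the
    maximum of the average perturbation-onset-vs-baseline (B vs A)
    trace.
    """
    t0 = traces_learning[0]
    avg_learn = np.mean([t.trace for t in traces_learning], axis=0)
    avg_fb = np.mean([t.trace for t in traces_feedback], axis=0)
    ff = ActivityChangeTrace(avg_learn, t0.dt, t0.go_step).peak_time_s()
    fb = ActivityChangeTrace(avg_fb, t0.dt, t0.go_step).peak_time_s()
    return ff, fb


def fb_ff_ratio(trace_overall: ActivityChangeTrace, ff_time_s: float,
                fb_time_s: float) -> float:
    """Ratio of the overall adaptation-related activity change at the
    feedback time point to that at the feedforward time point."""
    return trace_overall.value_at(fb_time_s) / trace_overall.value_at(ff_time_s)


# --------------------------------------------------------------------------
# unit-level classification

DEFAULT_WINDOWS = {"ff": (0.4, 0.6), "fb": (0.7, 0.9)}  # s after go


def _window_mean(res: TrialResult, dt: float, window: tuple) -> np.ndarray:
    go = int(round(res.trial.go_time / dt))
    i0 = go + int(round(window[0] / dt))
    i1 = go + int(round(window[1] / dt))
    return res.y[i0:i1].mean(axis=0)


def classify_units(
    params_baseline: NetworkParams,
    log: AdaptationLog,
    n_trials: int = 30,
    windows: dict = None,
    percentile: float = 95.0,
    n_null_resamples: int = 200,
    n_null_trials: int = 60,
    seed: int = 0,
    adaptation_phase: str = "perturbation",
) -> dict:
    """Classify units as feedback- and/or learning-responsive.

    A unit is *feedback*-responsive if its mean |activity change| in the
    late (0.8 +- 0.1 s after go) window over the first ``n_trials``
    adaptation trials — each compared to a matched baseline replay of
    the identical trial on the pre-adaptation weights — exceeds the
    ``percentile``-th percentile of its baseline-vs-baseline null.  It
    is *learning*-responsive analogously for the 0.5 +- 0.1 s window
    over the last ``n_trials`` adaptation trials.  The null is built
    from baseline-weight replays that differ only in the initial-state
    draw, resampled in groups of ``n_trials``, and calibrates the
    per-type false-positive rate at 1 - percentile/100.

    The session must have been run with window activity recording
    (``record_windows=DEFAULT_WINDOWS``).
    """
    windows = windows or DEFAULT_WINDOWS
    if log.window_activity is None:
        raise ValueError("session was run without record_windows")
    dt = params_baseline.dt
    recs = log.phase_records(adaptation_phase)
    offset = recs[0].global_index
    early = recs[:n_trials]
    late = recs[-n_trials:]

    def matched_change(subset, window_name):
        chg = []
        for rec in subset:
            base = replay_trial(params_baseline, rec, rotation_off=True)
            w_base = _window_mean(base, dt, windows[window_name])
            w_adapt = log.window_activity[window_name][rec.global_index]
            chg.append(np.abs(w_adapt - w_base))
        return np.mean(chg, axis=0)

    fb_change = matched_change(early, "fb")
    ff_change = matched_change(late, "ff")

    # baseline-vs-baseline null: identical trials, different initial state
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1313]))
    null_pairs = {nm: [] for nm in windows}
    null_recs = recs[:n_null_trials]
    for j, rec in enumerate(null_recs):
        alt_seed = int(np.random.SeedSequence(
            [log.master_seed, 1414, j]).generate_state(1)[0] % (2 ** 31))
        r1 = replay_trial(params_baseline, rec, rotation_off=True)
        r2 = replay_trial(params_baseline, rec, rotation_off=True,
                          init_seed=alt_seed)
        for nm, w in windows.items():
            null_pairs[nm].append(np.abs(_window_mean(r1, dt, w)
                                         - _window_mean(r2, dt, w)))
    thresholds = {}
    for nm in windows:
        pairs = np.asarray(null_pairs[nm])          # (n_pairs, N)
        draws = rng.integers(0, len(pairs),
                             size=(n_null_resamples, n_trials))
        null_stats = pairs[draws].mean(axis=1)      # (n_resamples, N)
        thresholds[nm] = np.percentile(null_stats, percentile, axis=0)

    is_fb = fb_change > thresholds["fb"]
    is_ff = ff_change > thresholds["ff"]
    labels = np.where(is_fb & is_ff, "both",
                      np.where(is_fb, "feedback",
                               np.where(is_ff, "learning", "neither")))
    n = len(labels)
    fractions = {k: float(np.sum(labels == k)) / n
                 for k in ("both", "feedback", "learning", "neither")}
    fractions["any_feedback"] = float(np.mean(is_fb))
    fractions["any_learning"] = float(np.mean(is_ff))
    return {"labels": labels, "fractions": fractions,
            "fb_change": fb_change, "ff_change": ff_change,
            "thresholds": thresholds}


def fb_ff_unit_correlation(classification: dict) -> tuple:
    """Pearson correlation, across dual-classified units, between the
    early-adaptation feedback-window change and the late-adaptation
    learning-window change.  Returns (r, p, n)."""
    mask = classification["labels"] == "both"
    n = int(mask.sum())
    if n < 3:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(classification["fb_change"][mask],
                          classification["ff_change"][mask])
    return float(r), float(p), n


# --------------------------------------------------------------------------
# velocity decoding

def _stack_lagged(ys, vs, unit_idx, lag_steps: int):
    X = np.concatenate([y[: len(y) - lag_steps or None, unit_idx]
                        for y in ys])
    Y = np.concatenate([v[lag_steps:] for v in vs])
    return X, Y


def fit_lag_decoder(results_y, results_v, unit_idx, lag_steps: int) -> Ridge:
    """Least-squares linear map from a unit subset's activity at t to the
    velocity at t + lag (tiny ridge for rank safety only)."""
    X, Y = _stack_lagged(results_y, results_v, unit_idx, lag_steps)
    dec = Ridge(alpha=1e-8)
    dec.fit(X, Y)
    return dec


def fit_velocity_decoder(
    trials: Sequence[TrialResult],
    unit_subset_size: int = 100,
    lags_s: Optional[Sequence[float]] = None,
    n_train: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Decoder accuracy (R^2, averaged over x/y) versus prediction lag.

    A fixed random subset of units is used (mimicking recordings from a
    limited population).  Trained on ``n_train`` trials, tested on the
    remaining disjoint trials; lags default to 0-0.3 s in dt steps.
    """
    dt = trials[0].trial.duration / len(trials[0].p_cursor)
    N = trials[0].y.shape[1]
    rng = np.random.default_rng(seed)
    unit_idx = np.sort(rng.choice(N, size=min(unit_subset_size, N),
                                  replace=False))
    if lags_s is None:
        lags_s = np.arange(0, 0.30 + 1e-9, dt)
    train = trials[:n_train]
    test = trials[n_train:]
    rows = []
    for lag in lags_s:
        L = int(round(lag / dt))
        dec = fit_lag_decoder([r.y for r in train], [r.v for r in train],
                              unit_idx, L)
        Xte, Yte = _stack_lagged([r.y for r in test], [r.v for r in test],
                                 unit_idx, L)
        rows.append({"lag_s": float(lag),
                     "r2": float(r2_score(Yte, dec.predict(Xte),
                                          multioutput="uniform_average"))})
    return pd.DataFrame(rows)


def decoder_backtest(
    log: AdaptationLog,
    unit_subset_size: int = 100,
    lag_s: float = 0.12,
    n_train_last: int = 100,
    seed: int = 0,
    adaptation_phase: str = "perturbation",
) -> pd.DataFrame:
    """Train a decoder on the last ``n_train_last`` adaptation trials and
    test it on each earlier adaptation trial separately.

    Requires the session to have been run with
    ``record_activity_phases=("perturbation",)``.  As the control policy
    is updated trial by trial, accuracy degrades toward the start of
    adaptation.
    """
    if log.activity is None:
        raise ValueError("session was run without activity recording")
    recs = log.phase_records(adaptation_phase)
    ys = [log.activity[r.global_index].astype(float) for r in recs]
    vs = [log.velocity[r.global_index].astype(float) for r in recs]
    first = recs[0]
    dt = first.spec.duration / len(ys[0])
    L = int(round(lag_s / dt))
    N = ys[0].shape[1]
    rng = np.random.default_rng(seed)
    unit_idx = np.sort(rng.choice(N, size=min(unit_subset_size, N),
                                  replace=False))
    dec = fit_lag_decoder(ys[-n_train_last:], vs[-n_train_last:],
                          unit_idx, L)
    rows = []
    for i, (y, v) in enumerate(zip(ys, vs)):
        Xte = y[: len(y) - L or None, unit_idx]
        Yte = v[L:]
        rows.append({"trial": recs[i].phase_index,
                     "r2": float(r2_score(Yte, dec.predict(Xte),
                                          multioutput="uniform_average")),
                     "in_training_window": i >= len(ys) - n_train_last})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# learning-timescale state-space fits

@dataclass
class StateSpaceFit:
    kind: str                 # "single" | "dual"
    params: dict              # A, B or A_f, A_s, B_f, B_s
    rss: float
    n: int

    @property
    def df(self) -> int:
        return 2 if self.kind == "single" else 4


@dataclass
class FTestResult:
    f_statistic: float
    p_value: float
    preferred_model: str      # "single" | "dual"


def prepare_adaptation_series(log: AdaptationLog,
                              rotation_deg: float) -> tuple:
    """(x, e) series from a session's perturbation phase.

    e(n): take-off angular error scaled by the rotation magnitude (so
    the initial error is ~1).  x(n): change in the *hand* take-off
    direction (the pre-rotation output, i.e. cursor direction minus the
    applied rotation) relative to the per-target baseline mean,
    normalised so that full adaptation (re-aiming by the rotation) is
    +1.
    """
    df = log.to_frame()
    base = df[df.phase == "baseline"].groupby("target_index")[
        "takeoff_angle_deg"].mean()
    pert = df[df.phase == "perturbation"]
    e = (pert.takeoff_error_deg / rotation_deg).to_numpy()
    hand = (pert.takeoff_angle_deg - pert.rotation_deg).to_numpy()
    tgts = pert.target_index.to_numpy()
    x = np.array([
        -((d - base.get(t, np.nan) + 180.0) % 360.0 - 180.0) / rotation_deg
        for d, t in zip(hand, tgts)])
    keep = np.isfinite(e) & np.isfinite(x)
    return x[keep], e[keep]


def _simulate_states(n, e, A_list, B_list):
    x = np.zeros(n)
    states = np.zeros(len(A_list))
    for i in range(n):
        x[i] = states.sum()
        states = np.asarray(A_list) * states + np.asarray(B_list) * e[i]
    return x


def _rss(theta, x_obs, e, kind):
    if kind == "single":
        A, B = theta
        pred = _simulate_states(len(x_obs), e, [A], [B])
    else:
        Af, As, Bf, Bs = theta
        pred = _simulate_states(len(x_obs), e, [Af, As], [Bf, Bs])
    return float(np.sum((pred - x_obs) ** 2))


def fit_single_rate(x_obs, e) -> StateSpaceFit:
    """Single-process fit x(n+1) = A x(n) + B e(n), A, B in [0, 1]."""
    x_obs, e = np.asarray(x_obs, float), np.asarray(e, float)
    if len(x_obs) < 3:
        raise ValueError("too few trials for a state-space fit")
    best = None
    for x0 in ([0.9, 0.1], [0.99, 0.01], [0.5, 0.5]):
        res = optimize.minimize(_rss, x0, args=(x_obs, e, "single"),
                                method="SLSQP",
                                bounds=[(0.0, 1.0)] * 2,
                                options={"maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    A, B = best.x
    return StateSpaceFit("single", {"A": float(A), "B": float(B)},
                         rss=float(best.fun), n=len(x_obs))


def fit_dual_rate(x_obs, e) -> StateSpaceFit:
    """Dual-process fit subject to A_f < A_s and B_f > B_s."""
    x_obs, e = np.asarray(x_obs, float), np.asarray(e, float)
    if len(x_obs) < 5:
        raise ValueError("too few trials for a state-space fit")
    cons = [
        {"type": "ineq", "fun": lambda th: th[1] - th[0] - 1e-4},  # As > Af
        {"type": "ineq", "fun": lambda th: th[2] - th[3] - 1e-4},  # Bf > Bs
    ]
    starts = [
        [0.92, 0.996, 0.03, 0.004],
        [0.8, 0.99, 0.1, 0.01],
        [0.5, 0.95, 0.2, 0.02],
        [0.95, 0.999, 0.01, 0.001],
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(_rss, x0, args=(x_obs, e, "dual"),
                                method="SLSQP",
                                bounds=[(0.0, 1.0)] * 4,
                                constraints=cons,
                                options={"maxiter": 500})
        if not res.success and not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    Af, As, Bf, Bs = best.x
    return StateSpaceFit("dual", {"A_f": float(Af), "A_s": float(As),
                                  "B_f": float(Bf), "B_s": float(Bs)},
                         rss=float(best.fun), n=len(x_obs))


def compare_models(fit_single: StateSpaceFit,
                   fit_dual: StateSpaceFit,
                   alpha: float = 0.05) -> FTestResult:
    """Nested-model F-test: does the dual-rate model fit significantly
    better than the single-rate model?"""
    n = fit_single.n
    df1, df2 = fit_single.df, fit_dual.df
    rss1, rss2 = fit_single.rss, fit_dual.rss
    if rss2 <= 0 or n <= df2:
        return FTestResult(float("inf"), 0.0, "dual")
    f = ((rss1 - rss2) / (df2 - df1)) / (rss2 / (n - df2))
    p = float(stats.f.sf(f, df2 - df1, n - df2))
    return FTestResult(float(f), p, "dual" if p < alpha else "single")


def simulate_dual_rate(A_f, A_s, B_f, B_s, n, noise_sd=0.0, seed=0,
                       perturbation=1.0):
    """Generate a synthetic adaptation series from the dual-rate model.

    Returns (x_obs, e_obs): the measured error is perturbation - x plus
    observation noise, and the measured adaptation is perturbation - e.
    """
    rng = np.random.default_rng(seed)
    xf = xs = 0.0
    e_obs = np.zeros(n)
    for i in range(n):
        x = xf + xs
        err = perturbation - x + rng.normal(0.0, noise_sd)
        e_obs[i] = err
        xf = A_f * xf + B_f * err
        xs = A_s * xs + B_s * err
    return perturbation - e_obs, e_obs


def simulate_single_rate(A, B, n, noise_sd=0.0, seed=0, perturbation=1.0):
    return simulate_dual_rate(A, 0.0, B, 0.0, n, noise_sd=noise_sd,
                              seed=seed, perturbation=perturbation)
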