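"""Feedback-driven local plasticity acting on the recurrent weights.

During adaptation the recurrent weight from unit *i* to unit *j* changes
in proportion to the delayed error feedback arriving at the postsynaptic
unit *j*, gated by the presynaptic eligibility trace (the within-trial
accumulation of unit *i*'s activity)::

    dW~_ji(t) = dt * eta * ( sum_k F_jk eps_k(t - delta) ) * r_i(t)

Increments are evaluated every fifth time step and summed until the end
of the trial; the accumulated change is applied to W once, between
trials.  Both pieces of information — the feedback drive a unit receives
and the presynaptic activity history — are locally available at the
synapse, which is what makes the rule biologically plausible.  The same
delayed, rotation-affected cursor error serves as the network input and
as the teacher term (one signal, two roles); on error-clamp trials both
are forced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import NetworkParams, TrialResult, run_trial
from .tasks import (StimulationSpec, TrialSpec, balanced_target_sequence,
                    make_centerout_trial)

__all__ = [
    "PlasticityConfig",
    "WeightDelta",
    "SessionPhase",
    "TrialRecord",
    "AdaptationLog",
    "plasticity_increment",
    "accumulate_and_apply",
    "run_adaptation",
    "replay_trial",
]


@dataclass
class PlasticityConfig:
    """Settings of the trial-by-trial plasticity rule.

    The effective speed of the rule is set by the product of eta with
    the network's trained signal scales (feedback drive, error magnitude
    and eligibility amplitude), so eta must be calibrated to the
    controller it is applied to.  The default is calibrated for networks
    trained by this package's curriculum, whose tight online error
    correction keeps the error-feedback teacher term small: it places
    adaptation to a 30 deg rotation on a ~100-200 trial timescale with a
    near-zero plateau and stable weights.
    """

    eta: float = 1e-3        # learning rate of the plasticity rule
    update_stride: int = 5   # steps between sampled increments
    enabled: bool = True

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.update_stride < 1:
            raise ValueError("update_stride must be >= 1")


@dataclass
class WeightDelta:
    """Accumulated recurrent weight change for one trial."""
    dW: np.ndarray
    trial_index: int = -1


def plasticity_increment(F: np.ndarray, delayed_error: np.ndarray,
                         r: np.ndarray, eta: float, dt: float) -> np.ndarray:
    """Single-step contribution: dt*eta * outer(F @ eps(t-delta), r(t))."""
    return dt * eta * np.outer(F @ np.asarray(delayed_error, float),
                               np.asarray(r, float))


def accumulate_and_apply(trial_run: TrialResult, config: PlasticityConfig,
                         params: NetworkParams) -> NetworkParams:
    """Sum the sampled increments of a completed trial and apply them to W.

    Uses the raw accumulator recorded during the trial when available,
    otherwise recomputes it from the stored eligibility and error time
    series.  Masked entries stay exactly zero.  Returns ``params``
    (mutated in place).
    """
    if not config.enabled or config.eta == 0.0:
        return params
    if trial_run.plasticity_accumulator is not None:
        acc = trial_run.plasticity_accumulator
    else:
        if trial_run.r is None:
            raise ValueError("trial must carry eligibility records or a "
                             "plasticity accumulator")
        acc = compute_accumulator(trial_run, params, config.update_stride)
    dW = params.dt * config.eta * acc
    if params.recurrent_mask is not None:
        dW = dW * params.recurrent_mask
    params.W = params.W + dW
    return params


def compute_accumulator(trial_run: TrialResult, params: NetworkParams,
                        stride: int = 5) -> np.ndarray:
    """Raw outer-product sum over sampled steps, from recorded series."""
    T = trial_run.epsilon.shape[0]
    D = params.delay_steps
    acc = np.zeros((params.N, params.N))
    if trial_run.trial.error_clamp:
        return acc
    for t in range(stride - 1, T, stride):
        if t - D < 0:
            continue
        e = trial_run.epsilon[t - D]
        acc += np.outer(params.F @ e, trial_run.r[t])
    return acc


def reaction_time(result: TrialResult) -> float:
    """Movement-initiation proxy: time (s) after the go cue at which
    cursor speed first exceeds 10% of the trial's peak speed."""
    dt = result.trial.duration / len(result.p_cursor)
    go = int(round(result.trial.go_time / dt))
    speed = result.cursor_speed()
    peak = speed[go:].max() if speed[go:].size else 0.0
    if peak <= 0:
        return float("nan")
    idx = np.nonzero(speed[go:] > 0.1 * peak)[0]
    return float(idx[0] * dt) if idx.size else float("nan")


# --------------------------------------------------------------------------
# adaptation sessions


@dataclass(frozen=True)
class SessionPhase:
    """One block of an adaptation session.

    ``rotation_sd_deg`` draws an independent per-trial rotation from
    Normal(rotation_deg, sd^2) (perturbation-consistency experiments).
    ``stimulation`` maps (index_in_phase, go_time) to an optional
    stimulation window.  ``targets`` restricts the centre-out target set
    (single-target adaptation).
    """
    name: str
    n_trials: int
    rotation_deg: float = 0.0
    rotation_sd_deg: float = 0.0
    plasticity_on: bool = False
    error_clamp: bool = False
    targets: Sequence[int] = tuple(range(8))
    stimulation: Optional[Callable[[int, float], Optional[StimulationSpec]]] = None

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("phase trial counts must be > 0")


@dataclass
class TrialRecord:
    global_index: int
    phase: str
    phase_index: int
    spec: TrialSpec
    init_seed: int
    takeoff_angle_deg: float
    takeoff_error_deg: float
    endpoint_error_cm: float
    reaction_time_s: float = float("nan")


@dataclass
class AdaptationLog:
    """Ordered per-trial records across a session, with weight snapshots.

    ``snapshots[k]`` holds the recurrent weights in effect *at* global
    trial k (before that trial's update).  Optional window-averaged or
    full activity records support the population analyses.
    """
    records: list = field(default_factory=list)
    snapshots: dict = field(default_factory=dict)
    params_final: Optional[NetworkParams] = None
    master_seed: int = 0
    window_activity: Optional[dict] = None   # name -> (n_trials, N) arrays
    activity: Optional[dict] = None          # global_index -> float32 (T, N)
    velocity: Optional[dict] = None          # global_index -> float32 (T, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append({
                "trial": rec.global_index,
                "phase": rec.phase,
                "phase_trial": rec.phase_index,
                "target_deg": rec.spec.target_angle_deg,
                "target_index": rec.spec.target_index,
                "rotation_deg": rec.spec.rotation_deg,
                "go_time": rec.spec.go_time,
                "takeoff_angle_deg": rec.takeoff_angle_deg,
                "takeoff_error_deg": rec.takeoff_error_deg,
                "endpoint_error_cm": rec.endpoint_error_cm,
                "seed": rec.init_seed,
            })
        return pd.DataFrame(rows)

    def errors(self, phase: str) -> np.ndarray:
        return np.array([r.takeoff_error_deg for r in self.records
                         if r.phase == phase])

    def phase_records(self, phase: str) -> list:
        return [r for r in self.records if r.phase == phase]


def _derived_seed(*key) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0]
               % (2 ** 31))


def build_phase_trials(phase: SessionPhase, phase_idx: int,
                       master_seed: int) -> list:
    """Deterministic (spec, init_seed) list for one phase."""
    rng = np.random.default_rng(
        np.random.SeedSequence([master_seed, 101, phase_idx]))
    targets = np.asarray(phase.targets)[
        balanced_target_sequence(phase.n_trials, rng) % len(phase.targets)]
    out = []
    for i in range(phase.n_trials):
        s_task = _derived_seed(master_seed, phase_idx, i, 0)
        s_init = _derived_seed(master_seed, phase_idx, i, 1)
        spec = make_centerout_trial(int(targets[i]), s_task)
        rot = phase.rotation_deg
        if phase.rotation_sd_deg > 0:
            rot = float(np.random.default_rng(
                np.random.SeedSequence([master_seed, phase_idx, i, 2])
            ).normal(phase.rotation_deg, phase.rotation_sd_deg))
        spec = spec.with_(rotation_deg=rot, error_clamp=phase.error_clamp)
        if phase.stimulation is not None:
            stim = phase.stimulation(i, spec.go_time)
            if stim is not None:
                spec = spec.with_(stimulation=stim)
        out.append((spec, s_init))
    return out


def run_adaptation(
    params: NetworkParams,
    phases: Sequence[SessionPhase],
    config: Optional[PlasticityConfig] = None,
    seed: int = 0,
    snapshot_every: int = 10,
    snapshot_trials: Sequence[int] = (),
    record_windows: Optional[dict] = None,
    record_activity_phases: Sequence[str] = (),
) -> AdaptationLog:
    """Run a multi-phase session with trial-by-trial plasticity.

    ``record_windows`` maps window names to (start_s, stop_s) relative to
    each trial's go cue; the per-unit mean activity in each window is
    stored for every trial.  ``record_activity_phases`` stores full
    float32 (T, N) activity and (T, 2) readout for every trial of the
    named phases (decoder analyses).  ``params`` is copied; the caller's
    weights are untouched.
    """
    config = config or PlasticityConfig()
    params = params.copy()
    log = AdaptationLog(master_seed=seed)
    if record_windows:
        log.window_activity = {nm: [] for nm in record_windows}
    if record_activity_phases:
        log.activity, log.velocity = {}, {}

    g = 0
    for phase_idx, phase in enumerate(phases):
        plastic = phase.plasticity_on and config.enabled and config.eta > 0
        for i, (spec, s_init) in enumerate(
                build_phase_trials(phase, phase_idx, seed)):
            if g in snapshot_trials or (
                    snapshot_every and g % snapshot_every == 0):
                log.snapshots[g] = params.W.copy()
            need_full = bool(record_windows) or phase.name in record_activity_phases
            res = run_trial(params, spec, s_init,
                            record_full=need_full,
                            accumulate_plasticity=plastic,
                            plasticity_stride=config.update_stride)
            if plastic:
                accumulate_and_apply(res, config, params)
            log.records.append(TrialRecord(
                global_index=g, phase=phase.name, phase_index=i, spec=spec,
                init_seed=s_init,
                takeoff_angle_deg=res.takeoff_angle_deg,
                takeoff_error_deg=res.takeoff_error_deg,
                endpoint_error_cm=res.endpoint_error_cm,
                reaction_time_s=reaction_time(res)))
            if record_windows:
                dt = params.dt
                go = int(round(spec.go_time / dt))
                for nm, (w0, w1) in record_windows.items():
                    i0, i1 = go + int(round(w0 / dt)), go + int(round(w1 / dt))
                    log.window_activity[nm].append(res.y[i0:i1].mean(axis=0))
            if phase.name in record_activity_phases:
                log.activity[g] = res.y.astype(np.float32)
                log.velocity[g] = res.v.astype(np.float32)
            g += 1

    if record_windows:
        log.window_activity = {nm: np.asarray(v)
                               for nm, v in log.window_activity.items()}
    log.params_final = params
    return log


def replay_trial(params: NetworkParams, record: TrialRecord,
                 rotation_off: bool = True, init_seed: Optional[int] = None,
                 record_full: bool = True) -> TrialResult:
    """Re-run a logged trial against given weights with plasticity off.

    With ``rotation_off`` the perturbation annotations are stripped
    (matched baseline probe); passing a different ``init_seed`` yields
    the initial-condition-only null comparison.
    """
    spec = record.spec
    if rotation_off:
        spec = spec.with_(rotation_deg=0.0, error_clamp=False,
                          stimulation=None)
    return run_trial(params, spec,
                     record.init_seed if init_seed is None else init_seed,
                     record_full=record_full)
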