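"""Scripted behavioural experiments over the closed-loop simulator.

Each experiment is a pure function of (weights, protocol, master seed):
visuomotor-rotation adaptation sessions with baseline / perturbation /
washout phases, frozen-weight epoch probes, policy-remap and
generalisation tests, perturbation-consistency sweeps, delay-period
stimulation, and error-clamp blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import NetworkParams, TrialResult, run_trial
from .plasticity import (AdaptationLog, PlasticityConfig, SessionPhase,
                         run_adaptation)
from .tasks import StimulationSpec, make_centerout_trial

__all__ = [
    "SessionProtocol",
    "PROBE_GO_TIME",
    "STIM_WINDOWS",
    "make_probe_trials",
    "probe_frozen",
    "vr_adaptation_session",
    "vr_epoch_probes",
    "policy_remap_experiment",
    "generalization_experiment",
    "variability_experiment",
    "stimulation_experiment",
    "error_clamp_experiment",
]

#: Fixed go time (s) for frozen probes, so step indices are commensurate
#: across trials when aligning activity to the go cue.
PROBE_GO_TIME = 1.45

#: Stimulation windows: label -> (onset relative to, offset_s, duration_s)
#: where onset is relative to trial start ("trial") or go cue ("go").
STIM_WINDOWS = {
    "target": ("trial", 0.0, 0.2),
    "go_cue": ("go", -0.2, 0.2),
    "movement_onset": ("go", 0.4, 0.2),
    "feedback": ("go", 0.65, 0.2),
}
STIM_AMPLITUDE = 0.1


@dataclass(frozen=True)
class SessionProtocol:
    """Ordered phases plus the master seed that reproduces the session."""
    phases: tuple
    master_seed: int = 0


def make_probe_trials(n_trials: int, seed: int,
                      go_time: float = PROBE_GO_TIME) -> list:
    """Matched seeded centre-out probe set: balanced targets, fixed go."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 909]))
    specs = []
    order = np.concatenate([rng.permutation(8)
                            for _ in range(int(np.ceil(n_trials / 8)))])
    for i in range(n_trials):
        spec = make_centerout_trial(int(order[i]), 0, go_time=go_time)
        init = int(np.random.SeedSequence([seed, 909, i]).generate_state(1)[0]
                   % (2 ** 31))
        specs.append((spec, init))
    return specs


def probe_frozen(params: NetworkParams, trial_set: Sequence,
                 rotation_deg: float = 0.0,
                 record_full: bool = True) -> list:
    """Run an identical seeded trial set against frozen weights
    (plasticity disabled), optionally under a visuomotor rotation."""
    out = []
    for spec, init_seed in trial_set:
        out.append(run_trial(params, spec.with_(rotation_deg=rotation_deg),
                             init_seed, record_full=record_full))
    return out


def _with_W(params: NetworkParams, W: np.ndarray) -> NetworkParams:
    p = params.copy()
    p.W = W.copy()
    return p


def vr_adaptation_session(
    params: NetworkParams,
    rotation_deg: float = 30.0,
    counts: tuple = (200, 500, 200),
    seed: int = 0,
    config: Optional[PlasticityConfig] = None,
    snapshot_every: int = 10,
    extra_snapshots: Sequence[int] = (),
    **kwargs,
) -> AdaptationLog:
    """Baseline -> perturbation -> washout session.

    Plasticity is on during the perturbation and washout phases.  Weight
    snapshots are always taken at perturbation onset and (when the
    perturbation phase is long enough) 300 trials into adaptation, the
    two epochs used by the activity-change analyses.
    """
    n_base, n_pert, n_wash = counts
    phases = [
        SessionPhase("baseline", n_base),
        SessionPhase("perturbation", n_pert, rotation_deg=rotation_deg,
                     plasticity_on=True),
    ]
    if n_wash > 0:
        phases.append(SessionPhase("washout", n_wash, plasticity_on=True))
    snaps = {n_base, n_base + min(300, n_pert)} | set(extra_snapshots)
    return run_adaptation(params, phases, config=config, seed=seed,
                          snapshot_every=snapshot_every,
                          snapshot_trials=sorted(snaps), **kwargs)


def vr_epoch_probes(
    params: NetworkParams,
    log: AdaptationLog,
    n_probe: int = 200,
    seed: int = 0,
    rotation_deg: float = 30.0,
    onset_trial: Optional[int] = None,
    late_trial: Optional[int] = None,
) -> dict:
    """Frozen-weight probes for the three behavioural epochs.

    The same seeded trials are run (A) without perturbation on the
    baseline weights, (B) under the rotation on the weights frozen at
    perturbation onset, and (C) under the rotation on the weights frozen
    after 300 adaptation trials.  Returns {"A": [...], "B": [...],
    "C": [...]} lists of :class:`TrialResult` with full activity.
    """
    n_base = sum(1 for r in log.records if r.phase == "baseline")
    onset_trial = n_base if onset_trial is None else onset_trial
    late_trial = (n_base + 300) if late_trial is None else late_trial
    probes = make_probe_trials(n_probe, seed)
    W0 = log.snapshots[0] if 0 in log.snapshots else log.snapshots[min(log.snapshots)]
    return {
        "A": probe_frozen(_with_W(params, W0), probes, rotation_deg=0.0),
        "B": probe_frozen(_with_W(params, log.snapshots[onset_trial]),
                          probes, rotation_deg=rotation_deg),
        "C": probe_frozen(_with_W(params, log.snapshots[late_trial]),
                          probes, rotation_deg=rotation_deg),
    }


def early_direction(result: TrialResult, latency_s: float = 0.25) -> float:
    """Direction (deg) of the cursor displacement from the go cue to a
    fixed early latency after it.

    Isolates the evoked movement plan: in rotation-off probes the
    delayed feedback starts re-correcting a remapped reach well before
    peak speed, so the peak-speed take-off angle underestimates the
    policy shift.
    """
    dt = result.trial.duration / len(result.p_cursor)
    go = int(round(result.trial.go_time / dt))
    d = result.p_cursor[go + int(round(latency_s / dt))] - result.p_cursor[go]
    return float(np.rad2deg(np.arctan2(d[1], d[0])))


def policy_remap_experiment(
    params: NetworkParams,
    seed: int = 0,
    rotation_deg: float = 45.0,
    n_adapt: int = 400,
    n_probe_reps: int = 5,
    config: Optional[PlasticityConfig] = None,
    latency_s: float = 0.25,
) -> pd.DataFrame:
    """Adapt fully to a target-spacing rotation, then probe baseline cues
    with the rotation removed and plasticity off.

    Reports, per target cue, the angular difference between the evoked
    early reach direction and the cue's baseline direction; full
    adaptation to a 45 deg rotation shifts reaches toward the adjacent
    target (shift ~ -rotation).
    """
    log = run_adaptation(
        params,
        [SessionPhase("perturbation", n_adapt, rotation_deg=rotation_deg,
                      plasticity_on=True)],
        config=config, seed=seed, snapshot_every=0, snapshot_trials=(0,))
    adapted = log.params_final
    rows = []
    for tgt in range(8):
        base_angs, adapt_angs = [], []
        for rep in range(n_probe_reps):
            spec = make_centerout_trial(tgt, 0, go_time=PROBE_GO_TIME)
            init = int(np.random.SeedSequence([seed, 411, tgt, rep])
                       .generate_state(1)[0] % (2 ** 31))
            base_angs.append(early_direction(
                run_trial(params, spec, init), latency_s))
            adapt_angs.append(early_direction(
                run_trial(adapted, spec, init), latency_s))
        base, adap = np.mean(base_angs), np.mean(adapt_angs)
        shift = (adap - base + 180.0) % 360.0 - 180.0
        rows.append({"target_index": tgt, "cue_deg": 45.0 * tgt,
                     "baseline_dir_deg": base, "adapted_dir_deg": adap,
                     "shift_deg": shift})
    return pd.DataFrame(rows)


def generalization_experiment(
    params: NetworkParams,
    adapted_target_index: int = 0,
    seed: int = 0,
    rotation_deg: float = 30.0,
    n_adapt: int = 400,
    n_probe_reps: int = 5,
    config: Optional[PlasticityConfig] = None,
    all_targets: bool = False,
) -> pd.DataFrame:
    """Adapt under the rotation on a single target (or all 8 with
    ``all_targets``), then probe every target under the rotation with
    plasticity off.

    Reports per probe target the mean |take-off error| before and after
    adaptation versus the angular distance from the adapted target.
    """
    targets = tuple(range(8)) if all_targets else (adapted_target_index,)
    log = run_adaptation(
        params,
        [SessionPhase("perturbation", n_adapt, rotation_deg=rotation_deg,
                      plasticity_on=True, targets=targets)],
        config=config, seed=seed, snapshot_every=0, snapshot_trials=(0,))
    adapted = log.params_final
    rows = []
    for tgt in range(8):
        errs_a, errs_u = [], []
        for rep in range(n_probe_reps):
            spec = make_centerout_trial(tgt, 0, go_time=PROBE_GO_TIME) \
                .with_(rotation_deg=rotation_deg)
            init = int(np.random.SeedSequence([seed, 511, tgt, rep])
                       .generate_state(1)[0] % (2 ** 31))
            errs_a.append(abs(run_trial(adapted, spec, init).takeoff_error_deg))
            errs_u.append(abs(run_trial(params, spec, init).takeoff_error_deg))
        dist = abs((45.0 * (tgt - adapted_target_index) + 180.0) % 360.0 - 180.0)
        rows.append({"target_index": tgt, "angular_distance_deg": dist,
                     "abs_error_adapted_deg": float(np.mean(errs_a)),
                     "abs_error_unadapted_deg": float(np.mean(errs_u))})
    return pd.DataFrame(rows)


def variability_experiment(
    params: NetworkParams,
    sigma_list_deg: Sequence[float] = (0.0, 4.0, 8.0, 12.0, 16.0),
    seed: int = 0,
    rotation_deg: float = 30.0,
    n_adapt: int = 400,
    n_final: int = 100,
    config: Optional[PlasticityConfig] = None,
) -> pd.DataFrame:
    """Adaptation under per-trial rotations ~ Normal(mean, sigma^2) for a
    sweep of sigma; reports the asymptotic mean |take-off error| over the
    final ``n_final`` trials.  Less consistent perturbations support less
    learning, so residual error grows with sigma."""
    rows = []
    for k, sd in enumerate(sigma_list_deg):
        log = run_adaptation(
            params,
            [SessionPhase("perturbation", n_adapt, rotation_deg=rotation_deg,
                          rotation_sd_deg=float(sd), plasticity_on=True)],
            config=config, seed=seed + k, snapshot_every=0)
        errs = np.abs(log.errors("perturbation")[-n_final:])
        rows.append({"sigma_deg": float(sd),
                     "asymptotic_abs_error_deg": float(np.nanmean(errs))})
    return pd.DataFrame(rows)


def _stim_schedule(window_label: str, amplitude: float = STIM_AMPLITUDE,
                   first: int = 10, last: int = 50, parity: int = 0):
    """Alternating stimulation assignment for trials [first, last):
    exactly 50% of those trials are stimulated."""
    ref, off, dur = STIM_WINDOWS[window_label]

    def fn(idx: int, go_time: float) -> Optional[StimulationSpec]:
        if not (first <= idx < last) or (idx - first) % 2 != parity:
            return None
        onset = off if ref == "trial" else go_time + off
        return StimulationSpec(label=window_label, onset=onset,
                               duration=dur, amplitude=amplitude)
    return fn


def stimulation_experiment(
    params: NetworkParams,
    window_label: str = "go_cue",
    seed: int = 0,
    rotation_deg: float = 30.0,
    n_adapt: int = 80,
    amplitude: float = STIM_AMPLITUDE,
    config: Optional[PlasticityConfig] = None,
    n_session_seeds: int = 2,
) -> dict:
    """Stimulate all units in a named window on alternating adaptation
    trials 10-49 and compare stimulated vs unstimulated trials.

    The alternating assignment guarantees exactly 50% stimulated trials;
    since trial parity can alias with the balanced target sequence, each
    session seed is run twice with the stimulated parity flipped and the
    groups are pooled, cancelling parity-linked bias.  Returns per-group
    mean current-trial |take-off error|, reaction time, and next-trial
    learning (|err(n)| - |err(n+1)|), plus the per-session logs.
    """
    groups = {"stim": {"err": [], "rt": [], "learn": []},
              "ctrl": {"err": [], "rt": [], "learn": []}}
    logs = []
    for k in range(n_session_seeds):
        for parity in (0, 1):
            phases = [SessionPhase(
                "perturbation", n_adapt, rotation_deg=rotation_deg,
                plasticity_on=True,
                stimulation=_stim_schedule(window_label, amplitude,
                                           parity=parity))]
            log = run_adaptation(params, phases, config=config,
                                 seed=seed + 1000 * k, snapshot_every=0)
            logs.append(log)
            recs = log.phase_records("perturbation")
            errs = np.array([r.takeoff_error_deg for r in recs])
            rts = np.array([r.reaction_time_s for r in recs])
            stim_mask = np.array([r.spec.stimulation is not None
                                  for r in recs])
            learning = np.abs(errs[:-1]) - np.abs(errs[1:])
            in_win = np.zeros(len(recs), bool)
            in_win[10:50] = True
            for name, mask in (("stim", stim_mask & in_win),
                               ("ctrl", ~stim_mask & in_win)):
                groups[name]["err"].extend(np.abs(errs[mask]))
                groups[name]["rt"].extend(rts[mask])
                groups[name]["learn"].extend(learning[mask[:-1]])
    summary = {"window": window_label, "amplitude": amplitude,
               "n_stim": len(groups["stim"]["err"]),
               "n_ctrl": len(groups["ctrl"]["err"])}
    for name in ("stim", "ctrl"):
        summary[f"abs_error_{name}_deg"] = float(
            np.mean(groups[name]["err"]))
        summary[f"reaction_time_{name}_s"] = float(
            np.nanmean(groups[name]["rt"]))
        summary[f"next_trial_learning_{name}_deg"] = float(
            np.mean(groups[name]["learn"]))
    return {"summary": summary, "logs": logs, "log": logs[0]}


def error_clamp_experiment(
    params: NetworkParams,
    seed: int = 0,
    rotation_deg: float = 30.0,
    counts: tuple = (40, 300, 20, 100),
    config: Optional[PlasticityConfig] = None,
) -> dict:
    """Adaptation, brief counter-perturbation, then an error-clamp block.

    During the clamp the fed-back error and the plasticity teacher term
    are both forced to zero, so the weights freeze and the adaptation
    state holds — no spontaneous-recovery rebound.  Returns the log and
    the adaptation variable (take-off direction change re baseline mean,
    per target) through the session.
    """
    n_base, n_adapt, n_counter, n_clamp = counts
    phases = [
        SessionPhase("baseline", n_base),
        SessionPhase("perturbation", n_adapt, rotation_deg=rotation_deg,
                     plasticity_on=True),
        SessionPhase("counter", n_counter, rotation_deg=-rotation_deg,
                     plasticity_on=True),
        SessionPhase("clamp", n_clamp, plasticity_on=True, error_clamp=True),
    ]
    log = run_adaptation(params, phases, config=config, seed=seed,
                         snapshot_every=0,
                         snapshot_trials=(n_base + n_adapt + n_counter,
                                          n_base + n_adapt + n_counter
                                          + n_clamp - 1))
    df = log.to_frame()
    base = df[df.phase == "baseline"].groupby("target_index")[
        "takeoff_angle_deg"].mean()
    df["adaptation_deg"] = [
        (row.takeoff_angle_deg - base.get(row.target_index, np.nan)
         + 180.0) % 360.0 - 180.0
        for row in df.itertuples()]
    return {"log": log, "frame": df}
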