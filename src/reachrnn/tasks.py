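"""Synthetic planar reaching trials: desired trajectories, stimulus
schedules, centre-out targets and perturbation annotations.

A trial lasts 3 s.  The 3-channel stimulus carries a 2-D target vector
(p_end - p_start), switched on 0.2 s after trial start, and a scalar
"hold" signal that stays at 1 until the go cue and 0 afterwards.  The
desired cursor trajectory interpolates between start and end points with
a logistic sigmoid f(u) = 1 / (1 + exp(-u * kappa)), kappa = 10 s^-1,
centred 0.5 s after the go cue, which yields a bell-shaped desired speed
profile of roughly 1 s duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "KAPPA",
    "SIGMOID_CENTER",
    "BumpSpec",
    "StimulationSpec",
    "TrialSpec",
    "desired_trajectory",
    "stimulus_schedule",
    "make_random_reach_trial",
    "make_centerout_trial",
    "apply_bump",
    "balanced_target_sequence",
]

KAPPA = 10.0            # sigmoid steepness (s^-1)
SIGMOID_CENTER = 0.5    # sigmoid midpoint, s after the go cue
WORKSPACE_HALF = 6.0    # random-reach start/end ~ U(-6, 6) cm per axis
CENTEROUT_RADIUS = 5.0  # cm

BUMP_PROB = 0.75
BUMP_AMPLITUDE = 10.0   # cm/s
BUMP_DURATION = 0.1     # s
BUMP_ONSET_RANGE = (0.2, 1.9)   # s after trial start


@dataclass(frozen=True)
class BumpSpec:
    """Velocity pulse added to the readout before rotation/integration."""
    axis: int            # 0 = x, 1 = y
    amplitude: float     # cm/s
    onset: float         # s after trial start
    duration: float      # s


@dataclass(frozen=True)
class StimulationSpec:
    """Uniform extra input to all units within a time window."""
    label: str
    onset: float         # s after trial start
    duration: float      # s
    amplitude: float


@dataclass(frozen=True)
class TrialSpec:
    """One trial's task definition (pure data; fully determines p*, s)."""

    p_start: np.ndarray
    p_end: np.ndarray
    go_time: float
    target_on: float = 0.2
    duration: float = 3.0
    hold_amplitude: float = 1.0
    bump: Optional[BumpSpec] = None
    rotation_deg: float = 0.0
    stimulation: Optional[StimulationSpec] = None
    error_clamp: bool = False
    target_index: Optional[int] = None   # set for centre-out trials

    def __post_init__(self):
        object.__setattr__(self, "p_start",
                           np.asarray(self.p_start, dtype=float))
        object.__setattr__(self, "p_end", np.asarray(self.p_end, dtype=float))
        if not (self.target_on <= self.go_time < self.duration):
            raise ValueError("need target_on <= go_time < duration")

    def with_(self, **kw) -> "TrialSpec":
        return replace(self, **kw)

    @property
    def target_angle_deg(self) -> float:
        d = self.p_end - self.p_start
        return float(np.rad2deg(np.arctan2(d[1], d[0])))

    def bump_profile(self, T: int, dt: float) -> Optional[np.ndarray]:
        if self.bump is None:
            return None
        prof = np.zeros((T, 2))
        i0 = int(round(self.bump.onset / dt))
        i1 = i0 + int(round(self.bump.duration / dt))
        prof[i0:i1, self.bump.axis] = self.bump.amplitude
        return prof

    def stimulation_profile(self, T: int, dt: float) -> Optional[np.ndarray]:
        if self.stimulation is None:
            return None
        prof = np.zeros(T)
        i0 = max(0, int(round(self.stimulation.onset / dt)))
        i1 = i0 + int(round(self.stimulation.duration / dt))
        prof[i0:i1] = self.stimulation.amplitude
        return prof


def desired_trajectory(trial: TrialSpec, dt: float) -> np.ndarray:
    """Per-step desired cursor positions p* (T, 2).

    p*(t) = p_start before go; afterwards the raw logistic interpolation
    p_start + f(t - go - 0.5 s) (p_end - p_start).  The unnormalised
    sigmoid leaves a ~0.7% offset at movement start and end.
    """
    T = int(round(trial.duration / dt))
    t = np.arange(T) * dt
    f = 1.0 / (1.0 + np.exp(-(t - trial.go_time - SIGMOID_CENTER) * KAPPA))
    f = np.where(t < trial.go_time, 0.0, f)
    if trial.go_time + 2 * SIGMOID_CENTER > trial.duration:
        warnings.warn("movement truncated: go_time + 1 s exceeds duration")
    return trial.p_start + f[:, None] * (trial.p_end - trial.p_start)


def stimulus_schedule(trial: TrialSpec, dt: float) -> np.ndarray:
    """Per-step 3-channel stimulus (T, 3).

    Channels 0-1: target vector p_end - p_start from target_on onwards
    (zero before).  Channel 2: hold signal, ``hold_amplitude`` until the
    go cue, 0 afterwards.
    """
    T = int(round(trial.duration / dt))
    t = np.arange(T) * dt
    s = np.zeros((T, 3))
    on = t >= trial.target_on
    s[on, 0:2] = trial.p_end - trial.p_start
    s[t < trial.go_time, 2] = trial.hold_amplitude
    return s


def make_random_reach_trial(seed) -> TrialSpec:
    """Random training reach: start/end ~ U(-6, 6) cm per component,
    go cue at 0.2 s + U(0, 1.5) s; no perturbations."""
    rng = np.random.default_rng(seed)
    p_start = rng.uniform(-WORKSPACE_HALF, WORKSPACE_HALF, 2)
    p_end = rng.uniform(-WORKSPACE_HALF, WORKSPACE_HALF, 2)
    go = 0.2 + rng.uniform(0.0, 1.5)
    return TrialSpec(p_start=p_start, p_end=p_end, go_time=go)


def make_centerout_trial(target_index: int, seed,
                         go_time: Optional[float] = None) -> TrialSpec:
    """Centre-out reach to one of 8 targets on the 5-cm circle.

    Target ``i`` sits at angle 45 deg * i from the +x axis.  The go cue
    is drawn uniformly from [1.2, 1.7] s unless fixed explicitly.
    """
    if not 0 <= int(target_index) <= 7:
        raise ValueError(f"target_index must be in 0..7, got {target_index}")
    ang = np.deg2rad(45.0 * int(target_index))
    p_end = CENTEROUT_RADIUS * np.array([np.cos(ang), np.sin(ang)])
    if go_time is None:
        go_time = float(np.random.default_rng(seed).uniform(1.2, 1.7))
    return TrialSpec(p_start=np.zeros(2), p_end=p_end, go_time=go_time,
                     target_index=int(target_index))


def apply_bump(trial: TrialSpec, seed) -> TrialSpec:
    """With probability 0.75, annotate the trial with a velocity pulse
    (10 cm/s, 0.1 s) on the x or y axis, onset ~ U(0.2, 1.9) s."""
    rng = np.random.default_rng(seed)
    if rng.random() >= BUMP_PROB:
        return trial
    axis = int(rng.integers(0, 2))
    onset = float(rng.uniform(*BUMP_ONSET_RANGE))
    return trial.with_(bump=BumpSpec(axis=axis, amplitude=BUMP_AMPLITUDE,
                                     onset=onset, duration=BUMP_DURATION))


def balanced_target_sequence(n_trials: int, rng) -> np.ndarray:
    """Pseudo-random centre-out target order in balanced blocks of 8."""
    n_blocks = int(np.ceil(n_trials / 8))
    seq = np.concatenate([rng.permutation(8) for _ in range(n_blocks)])
    return seq[:n_trials]
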