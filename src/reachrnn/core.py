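"""Discrete-time closed-loop simulation of the recurrent controller.

The network is a rate model of ``N`` rectified-linear units driven by a
3-channel stimulus (2-D target vector + hold signal), its own recurrent
activity, and a *delayed* copy of the cursor position error.  Its linear
readout is a 2-D velocity command that is integrated into a cursor
position; the mismatch between cursor and desired trajectory is the error
that is fed back after the sensory delay.  One forward-Euler step of the
dynamics::

    x(t+1) = x(t) + dt/tau * ( -x(t) + W y(t) + W_in s(t)
                               + F eps(t - delta) + b + u_stim(t) )
    y(t)   = max(0, x(t))
    v(t)   = W_out y(t) + b_out
    p(t)   = p(t-1) + dt * R(theta) (v(t) + bump(t))
    eps(t) = p_star(t) - p(t)

``R(theta)`` is the visuomotor rotation applied to the velocity command
before integration (identity when unperturbed), ``bump`` an optional
velocity pulse perturbation and ``u_stim`` an optional uniform extra input
to all units (stimulation experiments).  Eligibility traces
``r(t) = sum_{t'<t} y(t')`` accumulate activity within a trial and gate
the plasticity rule (see :mod:`reachrnn.plasticity`).

All times are stored in seconds (dt = 0.01 s, tau = 0.05 s,
delta = 0.12 s by default); positions are in cm and velocities in cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .tasks import TrialSpec, desired_trajectory, stimulus_schedule

__all__ = [
    "DEFAULTS",
    "NetworkParams",
    "NetworkState",
    "TrialResult",
    "init_params",
    "init_state",
    "step",
    "readout",
    "rotation_matrix",
    "integrate_position",
    "run_trial",
]

#: Simulation constants: default values of the published parameter table.
DEFAULTS = {
    "dt": 0.01,      # time step (s)
    "tau": 0.05,     # unit time constant (s)
    "delta": 0.12,   # feedback delay (s)
    "N": 400,        # number of units
    "T": 300,        # steps per trial (3 s at dt = 0.01 s)
    "x_init_range": 0.2,  # trial-start pre-activations ~ U(-0.2, 0.2)
}


@dataclass
class NetworkParams:
    """All weights, biases and architecture constants of the controller.

    Connectivity masks are applied multiplicatively and preserved under
    every weight update: a masked-out weight stays exactly zero.
    """

    W: np.ndarray          # recurrent weights (N, N)
    W_in: np.ndarray       # input weights (N, 3)
    W_out: np.ndarray      # readout weights (2, N), activity -> cm/s
    F: np.ndarray          # feedback weights (N, 2)
    b: np.ndarray          # unit bias (N,)
    b_out: np.ndarray      # readout bias (2,), cm/s
    dt: float = DEFAULTS["dt"]
    tau: float = DEFAULTS["tau"]
    delta: float = DEFAULTS["delta"]
    phi: str = "relu"
    recurrent_mask: Optional[np.ndarray] = None  # (N, N) binary
    feedback_mask: Optional[np.ndarray] = None   # (N, 2) binary

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau <= 0:
            raise ValueError("dt and tau must be positive")
        if self.phi != "relu":
            raise ValueError(f"unsupported nonlinearity: {self.phi!r}")
        steps = self.delta / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"feedback delay {self.delta} s is not an integer multiple "
                f"of dt {self.dt} s"
            )
        N = self.W.shape[0]
        if self.W.shape != (N, N) or self.W_in.shape != (N, 3) \
                or self.W_out.shape != (2, N) or self.F.shape != (N, 2) \
                or self.b.shape != (N,) or self.b_out.shape != (2,):
            raise ValueError("inconsistent parameter shapes")
        if self.recurrent_mask is not None:
            self.W = self.W * self.recurrent_mask
        if self.feedback_mask is not None:
            self.F = self.F * self.feedback_mask

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def delay_steps(self) -> int:
        return int(round(self.delta / self.dt))

    def copy(self) -> "NetworkParams":
        return replace(
            self,
            W=self.W.copy(), W_in=self.W_in.copy(), W_out=self.W_out.copy(),
            F=self.F.copy(), b=self.b.copy(), b_out=self.b_out.copy(),
            recurrent_mask=None if self.recurrent_mask is None
            else self.recurrent_mask.copy(),
            feedback_mask=None if self.feedback_mask is None
            else self.feedback_mask.copy(),
        )


def init_params(
    N: int = DEFAULTS["N"],
    seed: int = 0,
    recurrent_prob: float = 1.0,
    feedback_prob: float = 1.0,
    **kwargs,
) -> NetworkParams:
    """Random initial parameters: each tensor ~ U(-1/sqrt(l), 1/sqrt(l)).

    ``l`` is the unit count N for (W, W_in, F, b) and the output
    dimensionality 2 for (W_out, b_out).  Optional connection
    probabilities < 1 draw binary masks for the recurrent and feedback
    projections.
    """
    rng = np.random.default_rng(seed)
    sN, s2 = 1.0 / np.sqrt(N), 1.0 / np.sqrt(2)
    rmask = None
    fmask = None
    if recurrent_prob < 1.0:
        rmask = (rng.random((N, N)) < recurrent_prob).astype(float)
    if feedback_prob < 1.0:
        fmask = (rng.random((N, 2)) < feedback_prob).astype(float)
    return NetworkParams(
        W=rng.uniform(-sN, sN, (N, N)),
        W_in=rng.uniform(-sN, sN, (N, 3)),
        W_out=rng.uniform(-s2, s2, (2, N)),
        F=rng.uniform(-sN, sN, (N, 2)),
        b=rng.uniform(-sN, sN, N),
        b_out=rng.uniform(-s2, s2, 2),
        recurrent_mask=rmask,
        feedback_mask=fmask,
        **kwargs,
    )


@dataclass
class NetworkState:
    """Instantaneous simulation state (one network, one trial)."""

    x: np.ndarray            # pre-activations (N,)
    y: np.ndarray            # activities, y = max(0, x)
    r: np.ndarray            # eligibility trace, r(t) = sum_{t'<t} y(t')
    p: np.ndarray            # cursor position (2,), cm
    step_index: int = 0


def init_state(params: NetworkParams, seed: int, start_position) -> NetworkState:
    """Trial-start state: x ~ U(-0.2, 0.2) i.i.d., r = 0, p = start point."""
    rng = np.random.default_rng(seed)
    a = DEFAULTS["x_init_range"]
    x = rng.uniform(-a, a, params.N)
    return NetworkState(
        x=x,
        y=np.maximum(x, 0.0),
        r=np.zeros(params.N),
        p=np.asarray(start_position, dtype=float).copy(),
    )


def step(
    state: NetworkState,
    params: NetworkParams,
    stimulus: np.ndarray,
    delayed_error: np.ndarray,
    extra_input: float = 0.0,
) -> NetworkState:
    """One forward-Euler update of the unit dynamics.

    ``delayed_error`` is eps(t - delta), taken as the zero vector whenever
    t - delta precedes the trial start.  ``extra_input`` is added
    uniformly to all units inside the Euler bracket, exactly like the
    bias (stimulation experiments; 0 otherwise).  The cursor position is
    *not* advanced here — output integration is a separate operation.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    delayed_error = np.asarray(delayed_error, dtype=float)
    if stimulus.shape != (3,):
        raise ValueError(f"stimulus must be a 3-vector, got {stimulus.shape}")
    if delayed_error.shape != (2,):
        raise ValueError(
            f"delayed_error must be a 2-vector, got {delayed_error.shape}")
    a = params.dt / params.tau
    drive = (params.W @ state.y + params.W_in @ stimulus
             + params.F @ delayed_error + params.b + extra_input)
    x = state.x + a * (-state.x + drive)
    return NetworkState(
        x=x,
        y=np.maximum(x, 0.0),
        r=state.r + state.y,
        p=state.p.copy(),
        step_index=state.step_index + 1,
    )


def readout(y: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Linear velocity readout v = W_out y + b_out (cm/s)."""
    return params.W_out @ y + params.b_out


def rotation_matrix(angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def integrate_position(p_prev, v, dt: float, rotation_deg: float = 0.0) -> np.ndarray:
    """Advance the cursor: p = p_prev + dt * R(theta) v.

    ``rotation_deg`` is the active visuomotor rotation of the velocity
    command about the origin (0 when unperturbed).  The returned cursor
    position is the one used for the error signal and all behavioural
    metrics.
    """
    v = np.asarray(v, dtype=float)
    if rotation_deg != 0.0:
        v = rotation_matrix(rotation_deg) @ v
    return np.asarray(p_prev, dtype=float) + dt * v


@dataclass
class TrialResult:
    """Full within-trial record plus scalar summaries.

    All per-step arrays have length T = duration / dt; step 0 is the
    initial condition (p = start point).  ``v`` is the raw network
    readout (before bump injection and rotation); ``p_cursor`` reflects
    both.  ``epsilon`` always equals ``p_star - p_cursor`` exactly, even
    on error-clamp trials (where the *fed-back* error is zeroed).
    """

    trial: TrialSpec
    seed: int
    takeoff_angle_deg: float
    takeoff_error_deg: float
    endpoint_error_cm: float
    p_cursor: np.ndarray                  # (T, 2)
    p_star: np.ndarray                    # (T, 2)
    epsilon: np.ndarray                   # (T, 2)
    v: np.ndarray                         # (T, 2) network readout
    x: Optional[np.ndarray] = None        # (T, N) if record_full
    y: Optional[np.ndarray] = None        # (T, N) if record_full
    r: Optional[np.ndarray] = None        # (T, N) if record_full
    plasticity_accumulator: Optional[np.ndarray] = field(
        default=None, repr=False)        # (N, N) raw outer-product sum

    @property
    def go_step(self) -> int:
        return int(round(self.trial.go_time / (self.trial.duration / len(self.p_cursor))))

    def cursor_speed(self) -> np.ndarray:
        """Per-step cursor speed ||p(t) - p(t-1)|| / dt (cm/s); 0 at t=0."""
        dt = self.trial.duration / len(self.p_cursor)
        sp = np.zeros(len(self.p_cursor))
        sp[1:] = np.linalg.norm(np.diff(self.p_cursor, axis=0), axis=1) / dt
        return sp


def _takeoff(p_cursor: np.ndarray, trial: TrialSpec, dt: float):
    """Take-off angle (deg): direction of the cursor displacement between
    the go cue and the moment of peak cursor speed."""
    go = int(round(trial.go_time / dt))
    speed = np.linalg.norm(np.diff(p_cursor, axis=0), axis=1)
    seg = speed[go:]
    if seg.size == 0 or seg.max() <= 0:
        return np.nan, np.nan
    t_peak = go + 1 + int(np.argmax(seg))
    disp = p_cursor[t_peak] - p_cursor[go]
    if np.linalg.norm(disp) == 0:
        return np.nan, np.nan
    ang = np.rad2deg(np.arctan2(disp[1], disp[0]))
    target = trial.p_end - trial.p_start
    tang = np.rad2deg(np.arctan2(target[1], target[0]))
    err = (ang - tang + 180.0) % 360.0 - 180.0
    if err == -180.0:
        err = 180.0
    return ang, err


def run_trial(
    params: NetworkParams,
    trial: TrialSpec,
    seed: int,
    record_full: bool = False,
    feedback_on: bool = True,
    accumulate_plasticity: bool = False,
    plasticity_stride: int = 5,
) -> TrialResult:
    """Execute one full closed-loop trial (T = duration/dt steps).

    Applies the trial's stimulus schedule and any bump / rotation /
    stimulation / error-clamp annotations.  Deterministic given
    (params, trial, seed).  When ``accumulate_plasticity`` the raw
    outer-product sum of the plasticity rule, sampled every
    ``plasticity_stride`` steps, is returned in the result (the caller
    scales by dt*eta and applies it; see :mod:`reachrnn.plasticity`).
    """
    dt, N = params.dt, params.N
    T_f = trial.duration / dt
    if abs(T_f - round(T_f)) > 1e-9:
        raise ValueError("trial duration is not divisible by dt")
    T = int(round(T_f))
    D = params.delay_steps
    a = dt / params.tau

    p_star = desired_trajectory(trial, dt)
    s = stimulus_schedule(trial, dt)
    bump_v = trial.bump_profile(T, dt)          # (T, 2) or None
    stim_u = trial.stimulation_profile(T, dt)   # (T,) or None
    R = rotation_matrix(trial.rotation_deg) if trial.rotation_deg else None

    rng = np.random.default_rng(seed)
    x = rng.uniform(-DEFAULTS["x_init_range"], DEFAULTS["x_init_range"], N)
    y = np.maximum(x, 0.0)
    r = np.zeros(N)
    p = trial.p_start.astype(float).copy()

    eps = np.zeros((T, 2))
    eps_fb = np.zeros((T, 2))   # the error actually fed back (0 on clamp)
    v_out = np.zeros((T, 2))
    p_rec = np.zeros((T, 2))
    if record_full:
        x_rec = np.zeros((T, N))
        y_rec = np.zeros((T, N))
        r_rec = np.zeros((T, N))
        x_rec[0], y_rec[0], r_rec[0] = x, y, r
    acc = np.zeros((N, N)) if accumulate_plasticity else None

    v_out[0] = params.W_out @ y + params.b_out
    p_rec[0] = p
    eps[0] = p_star[0] - p
    if not trial.error_clamp:
        eps_fb[0] = eps[0]

    zero2 = np.zeros(2)
    for t in range(1, T):
        e_del = eps_fb[t - 1 - D] if (t - 1 - D) >= 0 else zero2
        if not feedback_on:
            e_del = zero2
        u = stim_u[t - 1] if stim_u is not None else 0.0
        drive = (params.W @ y + params.W_in @ s[t - 1]
                 + params.F @ e_del + params.b + u)
        x = x + a * (-x + drive)
        r = r + y
        y = np.maximum(x, 0.0)
        v = params.W_out @ y + params.b_out
        v_cmd = v + bump_v[t] if bump_v is not None else v
        if R is not None:
            v_cmd = R @ v_cmd
        p = p + dt * v_cmd
        v_out[t] = v
        p_rec[t] = p
        eps[t] = p_star[t] - p
        if not trial.error_clamp:
            eps_fb[t] = eps[t]
        if record_full:
            x_rec[t], y_rec[t], r_rec[t] = x, y, r
        if acc is not None and (t + 1) % plasticity_stride == 0:
            e_pl = eps_fb[t - D] if t - D >= 0 else zero2
            if feedback_on and e_pl.any():
                acc += np.outer(params.F @ e_pl, r)

    angle, err = _takeoff(p_rec, trial, dt)
    endpoint = float(np.linalg.norm(p_rec[-1] - trial.p_end))
    return TrialResult(
        trial=trial, seed=seed,
        takeoff_angle_deg=angle, takeoff_error_deg=err,
        endpoint_error_cm=endpoint,
        p_cursor=p_rec, p_star=p_star, epsilon=eps, v=v_out,
        x=x_rec if record_full else None,
        y=y_rec if record_full else None,
        r=r_rec if record_full else None,
        plasticity_accumulator=acc,
    )
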