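"""Gradient-based initial training of the closed-loop controller.

The network is trained end-to-end through the *closed* sensorimotor loop:
gradients are propagated through the recurrent dynamics, the readout, the
cursor integration and the delayed error-feedback path (no truncation).
The loss combines the time-averaged squared position error, an unsquared
L2 (Frobenius) norm penalty on every parameter tensor, and a mean squared
activity penalty::

    L = 1/(2 B T) sum_{b,t,k} eps_k(t,b)^2
        + beta * sum_M ||M||_2
        + gamma / (N B T) * sum_{b,t,i} y_i(t,b)^2

Optimisation uses Adam (alpha = 0.001, beta1 = 0.9, beta2 = 0.999) with
the global gradient norm clipped at 0.2 before each update.  The
curriculum has three blocks (default 100, 500, 500 epochs): feedback
weights F frozen, then all parameters plastic, then all plastic with
random velocity-bump perturbations so the network learns online
correction.  One epoch is one batch of B = 20 freshly generated trials.

Backpropagation through time is implemented analytically in numpy; the
adjoint recursion is validated against finite differences in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DEFAULTS, NetworkParams, init_params, rotation_matrix
from .tasks import (TrialSpec, apply_bump, desired_trajectory,
                    make_centerout_trial, make_random_reach_trial,
                    stimulus_schedule)

__all__ = [
    "TrainingConfig",
    "LossBreakdown",
    "run_batch",
    "compute_loss",
    "loss_and_gradients",
    "train_initial",
    "train_no_feedback",
    "train_no_recurrence",
    "adapt_by_gradient_descent",
    "random_reach_generator",
]

PARAM_NAMES = ("W", "W_in", "W_out", "F", "b", "b_out")


@dataclass
class TrainingConfig:
    alpha: float = 0.001          # Adam learning rate
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 20
    weight_reg: float = 0.001     # beta
    activity_reg: float = 0.002   # gamma
    grad_clip_norm: float = 0.2
    epochs_per_block: tuple = (100, 500, 500)
    seed: int = 0


@dataclass
class LossBreakdown:
    error_term: float
    weight_term: float
    activity_term: float

    @property
    def total(self) -> float:
        return self.error_term + self.weight_term + self.activity_term


@dataclass
class BatchCache:
    """Forward-pass tensors needed by the adjoint recursion.

    Time-major arrays: xs, ys (T, B, N); eps, e_used, vs (T, B, 2);
    s (T, B, 3).  ``e_used[t]`` is the delayed error that entered the
    Euler bracket at step t (zero before the delay or with feedback off).
    """
    xs: np.ndarray
    ys: np.ndarray
    vs: np.ndarray
    eps: np.ndarray
    e_used: np.ndarray
    s: np.ndarray
    rot: np.ndarray          # (B, 2, 2) per-trial rotation matrices
    clamp: np.ndarray        # (B,) bool, error-clamped trials
    feedback_on: bool


def _trial_inputs(trials: Sequence[TrialSpec], dt: float):
    T = int(round(trials[0].duration / dt))
    B = len(trials)
    p_star = np.zeros((T, B, 2))
    s = np.zeros((T, B, 3))
    bump = np.zeros((T, B, 2))
    stim = np.zeros((T, B))
    rot = np.zeros((B, 2, 2))
    p0 = np.zeros((B, 2))
    for i, tr in enumerate(trials):
        p_star[:, i] = desired_trajectory(tr, dt)
        s[:, i] = stimulus_schedule(tr, dt)
        bp = tr.bump_profile(T, dt)
        if bp is not None:
            bump[:, i] = bp
        sp = tr.stimulation_profile(T, dt)
        if sp is not None:
            stim[:, i] = sp
        rot[i] = rotation_matrix(tr.rotation_deg)
        p0[i] = tr.p_start
    return T, p_star, s, bump, stim, rot, p0


def run_batch(
    params: NetworkParams,
    trials: Sequence[TrialSpec],
    seeds: Sequence[int],
    feedback_on: bool = True,
) -> BatchCache:
    """Vectorised closed-loop forward pass over a batch of trials.

    Semantically identical to running :func:`reachrnn.core.run_trial` on
    each (trial, seed) pair; the equivalence is asserted in the tests.
    """
    dt, N, D = params.dt, params.N, params.delay_steps
    a = dt / params.tau
    B = len(trials)
    T, p_star, s, bump, stim, rot, p = _trial_inputs(trials, dt)
    p = p.copy()

    xs = np.zeros((T, B, N))
    ys = np.zeros((T, B, N))
    vs = np.zeros((T, B, 2))
    eps = np.zeros((T, B, 2))
    e_used = np.zeros((T, B, 2))

    x0 = np.stack([
        np.random.default_rng(sd).uniform(
            -DEFAULTS["x_init_range"], DEFAULTS["x_init_range"], N)
        for sd in seeds])
    xs[0] = x0
    ys[0] = np.maximum(x0, 0.0)
    vs[0] = ys[0] @ params.W_out.T + params.b_out
    eps[0] = p_star[0] - p

    clamp = np.array([tr.error_clamp for tr in trials])[:, None]
    eps_fb0 = np.where(clamp, 0.0, eps[0])
    eps_fb = np.zeros((T, B, 2))
    eps_fb[0] = eps_fb0

    for t in range(1, T):
        if feedback_on and t - 1 - D >= 0:
            e_del = eps_fb[t - 1 - D]
        else:
            e_del = np.zeros((B, 2))
        e_used[t] = e_del
        drive = (ys[t - 1] @ params.W.T + s[t - 1] @ params.W_in.T
                 + e_del @ params.F.T + params.b + stim[t - 1][:, None])
        xs[t] = xs[t - 1] + a * (-xs[t - 1] + drive)
        ys[t] = np.maximum(xs[t], 0.0)
        vs[t] = ys[t] @ params.W_out.T + params.b_out
        v_cmd = vs[t] + bump[t]
        v_rot = np.einsum("bij,bj->bi", rot, v_cmd)
        p = p + dt * v_rot
        eps[t] = p_star[t] - p
        eps_fb[t] = np.where(clamp, 0.0, eps[t])

    return BatchCache(xs=xs, ys=ys, vs=vs, eps=eps, e_used=e_used, s=s,
                      rot=rot, clamp=clamp[:, 0], feedback_on=feedback_on)


def _loss_from_arrays(eps, ys, params, config) -> LossBreakdown:
    T, B = eps.shape[0], eps.shape[1]
    N = ys.shape[2]
    err = float(np.sum(eps ** 2) / (2.0 * B * T))
    wt = float(config.weight_reg * sum(
        np.linalg.norm(getattr(params, nm)) for nm in PARAM_NAMES))
    act = float(config.activity_reg * np.sum(ys ** 2) / (N * B * T))
    return LossBreakdown(err, wt, act)


def compute_loss(batch_results, params: NetworkParams,
                 config: TrainingConfig) -> LossBreakdown:
    """Loss breakdown for a batch of completed trials.

    ``batch_results`` may be a list of :class:`TrialResult` with full
    time series, or a :class:`BatchCache`.
    """
    if isinstance(batch_results, BatchCache):
        return _loss_from_arrays(batch_results.eps, batch_results.ys,
                                 params, config)
    if not batch_results:
        raise ValueError("empty batch")
    eps = np.stack([r.epsilon for r in batch_results], axis=1)
    if batch_results[0].y is None:
        raise ValueError("trial results must carry full time series")
    ys = np.stack([r.y for r in batch_results], axis=1)
    return _loss_from_arrays(eps, ys, params, config)


def loss_and_gradients(
    params: NetworkParams,
    cache: BatchCache,
    config: TrainingConfig,
) -> tuple[LossBreakdown, dict]:
    """Analytic adjoint (BPTT) pass through the closed loop.

    Returns the loss breakdown and per-tensor gradients of the *total*
    loss, including the feedback path eps(t) -> x(t + 1 + delay) when
    feedback is on.
    """
    dt, N, D = params.dt, params.N, params.delay_steps
    a = dt / params.tau
    T, B = cache.xs.shape[0], cache.xs.shape[1]
    loss = _loss_from_arrays(cache.eps, cache.ys, params, config)

    gx = np.zeros((T, B, N))
    gv = np.zeros((T, B, 2))
    gp_next = np.zeros((B, 2))
    err_scale = 1.0 / (B * T)
    act_scale = 2.0 * config.activity_reg / (N * B * T)

    for t in range(T - 1, -1, -1):
        ge = cache.eps[t] * err_scale
        if cache.feedback_on and t + 1 + D <= T - 1:
            fb = a * (gx[t + 1 + D] @ params.F)
            fb[cache.clamp] = 0.0  # clamped trials feed back zero error
            ge = ge + fb
        gp = -ge + gp_next
        if t > 0:
            # p(t) = p(t-1) + dt * R v_cmd(t)  =>  gv = dt * R^T gp
            gv[t] = dt * np.einsum("bij,bi->bj", cache.rot, gp)
        gy = gv[t] @ params.W_out + act_scale * cache.ys[t]
        if t < T - 1:
            gy = gy + a * (gx[t + 1] @ params.W)
        gxt = gy * (cache.xs[t] > 0)
        if t < T - 1:
            gxt = gxt + (1.0 - a) * gx[t + 1]
        gx[t] = gxt
        gp_next = gp

    def _flat(arr3):  # (T, B, K) -> (T*B, K)
        return arr3.reshape(-1, arr3.shape[-1])

    gxf = _flat(gx[1:])
    grads = {
        "W": a * gxf.T @ _flat(cache.ys[:-1]),
        "W_in": a * gxf.T @ _flat(cache.s[:-1]),
        "F": a * gxf.T @ _flat(cache.e_used[1:]),
        "b": a * gx[1:].sum(axis=(0, 1)),
        "W_out": _flat(gv).T @ _flat(cache.ys),
        "b_out": gv.sum(axis=(0, 1)),
    }
    # unsquared-norm regulariser: d||M||/dM = M / ||M||
    for nm in PARAM_NAMES:
        M = getattr(params, nm)
        norm = np.linalg.norm(M)
        if norm > 0:
            grads[nm] = grads[nm] + config.weight_reg * M / norm
    if params.recurrent_mask is not None:
        grads["W"] *= params.recurrent_mask
    if params.feedback_mask is not None:
        grads["F"] *= params.feedback_mask
    return loss, grads


def _clip_global_norm(grads: dict, names: Iterable[str], max_norm: float):
    total = np.sqrt(sum(float(np.sum(grads[nm] ** 2)) for nm in names))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for nm in names:
            grads[nm] = grads[nm] * scale
    return total


class _Adam:
    def __init__(self, config: TrainingConfig):
        self.cfg = config
        self.m = {}
        self.v = {}
        self.t = 0

    def step(self, params: NetworkParams, grads: dict,
             trainable: Sequence[str]) -> None:
        c = self.cfg
        self.t += 1
        for nm in trainable:
            g = grads[nm]
            if nm not in self.m:
                self.m[nm] = np.zeros_like(g)
                self.v[nm] = np.zeros_like(g)
            self.m[nm] = c.adam_beta1 * self.m[nm] + (1 - c.adam_beta1) * g
            self.v[nm] = c.adam_beta2 * self.v[nm] + (1 - c.adam_beta2) * g ** 2
            mhat = self.m[nm] / (1 - c.adam_beta1 ** self.t)
            vhat = self.v[nm] / (1 - c.adam_beta2 ** self.t)
            upd = c.alpha * mhat / (np.sqrt(vhat) + c.adam_eps)
            setattr(params, nm, getattr(params, nm) - upd)
        if params.recurrent_mask is not None:
            params.W *= params.recurrent_mask
        if params.feedback_mask is not None:
            params.F *= params.feedback_mask


def random_reach_generator(config: TrainingConfig,
                           bumps: bool = False) -> Callable:
    """Default epoch generator: B fresh random reaches (+ optional bumps).

    Returns ``gen(epoch) -> (trials, init_seeds)``; everything is a pure
    function of (config.seed, epoch) so any epoch is reproducible in
    isolation.
    """
    def gen(epoch: int):
        trials, seeds = [], []
        for i in range(config.batch_size):
            ss = np.random.SeedSequence([config.seed, epoch, i])
            s_task, s_bump, s_init = ss.spawn(3)
            tr = make_random_reach_trial(s_task)
            if bumps:
                tr = apply_bump(tr, s_bump)
            trials.append(tr)
            seeds.append(s_init)
        return trials, seeds
    return gen


def _train_loop(params, config, blocks, history, adam=None):
    """blocks: list of (n_epochs, trainable_names, generator, feedback_on)."""
    adam = adam or _Adam(config)
    epoch = len(history)
    for n_epochs, trainable, gen, fb_on in blocks:
        for _ in range(n_epochs):
            trials, seeds = gen(epoch)
            cache = run_batch(params, trials, seeds, feedback_on=fb_on)
            loss, grads = loss_and_gradients(params, cache, config)
            if not np.isfinite(loss.total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.total}")
            _clip_global_norm(grads, trainable, config.grad_clip_norm)
            adam.step(params, grads, trainable)
            history.append({"epoch": epoch, "error_term": loss.error_term,
                            "weight_term": loss.weight_term,
                            "activity_term": loss.activity_term,
                            "total": loss.total})
            epoch += 1
    return params


def train_initial(
    config: TrainingConfig,
    task_generator: Optional[Callable] = None,
    n_units: int = DEFAULTS["N"],
    params: Optional[NetworkParams] = None,
    recurrent_prob: float = 1.0,
    feedback_prob: float = 1.0,
    return_history: bool = False,
):
    """Three-block curriculum training of the closed-loop controller.

    Block 1 freezes the feedback weights F (the network first learns
    feedforward control); block 2 releases all parameters; block 3 adds
    random velocity-bump perturbations so the feedback pathway learns
    online correction.
    """
    if params is None:
        params = init_params(n_units, seed=config.seed,
                             recurrent_prob=recurrent_prob,
                             feedback_prob=feedback_prob)
    gen_plain = task_generator or random_reach_generator(config, bumps=False)
    gen_bump = task_generator or random_reach_generator(config, bumps=True)
    n1, n2, n3 = config.epochs_per_block
    all_p = list(PARAM_NAMES)
    no_F = [nm for nm in all_p if nm != "F"]
    history: list = []
    _train_loop(params, config, [
        (n1, no_F, gen_plain, True),
        (n2, all_p, gen_plain, True),
        (n3, all_p, gen_bump, True),
    ], history)
    if return_history:
        return params, pd.DataFrame(history)
    return params


def train_no_feedback(config: TrainingConfig, n_units: int = DEFAULTS["N"],
                      return_history: bool = False):
    """Control model: identical curriculum with the feedback path removed
    (F pinned at 0, no error input)."""
    params = init_params(n_units, seed=config.seed)
    params.F = np.zeros_like(params.F)
    gen_plain = random_reach_generator(config, bumps=False)
    gen_bump = random_reach_generator(config, bumps=True)
    n1, n2, n3 = config.epochs_per_block
    no_F = [nm for nm in PARAM_NAMES if nm != "F"]
    history: list = []
    _train_loop(params, config, [
        (n1, no_F, gen_plain, False),
        (n2, no_F, gen_plain, False),
        (n3, no_F, gen_bump, False),
    ], history)
    if return_history:
        return params, pd.DataFrame(history)
    return params


def train_no_recurrence(config: TrainingConfig, n_units: int = DEFAULTS["N"],
                        return_history: bool = False):
    """Control model: identical curriculum with W pinned at 0."""
    params = init_params(n_units, seed=config.seed)
    params.recurrent_mask = np.zeros_like(params.W)
    params.W = np.zeros_like(params.W)
    gen_plain = random_reach_generator(config, bumps=False)
    gen_bump = random_reach_generator(config, bumps=True)
    n1, n2, n3 = config.epochs_per_block
    no_F = [nm for nm in PARAM_NAMES if nm != "F"]
    all_p = list(PARAM_NAMES)
    history: list = []
    _train_loop(params, config, [
        (n1, no_F, gen_plain, True),
        (n2, all_p, gen_plain, True),
        (n3, all_p, gen_bump, True),
    ], history)
    if return_history:
        return params, pd.DataFrame(history)
    return params


def adapt_by_gradient_descent(
    params: NetworkParams,
    rotation_deg: float = 30.0,
    n_epochs: int = 100,
    config: Optional[TrainingConfig] = None,
    seed: int = 0,
    snapshot_epochs: Sequence[int] = (),
):
    """Control adaptation: Adam updates of W on the position-error loss,
    with the online feedback input disabled during these runs.

    Used to generate the comparison models whose activity change lacks
    the late feedback peak.  Returns (params, history, snapshots).
    """
    config = config or TrainingConfig(seed=seed)
    params = params.copy()

    def gen(epoch: int):
        trials, seeds = [], []
        for i in range(config.batch_size):
            ss = np.random.SeedSequence([seed, 7001, epoch, i])
            s_task, s_init = ss.spawn(2)
            rng = np.random.default_rng(s_task)
            tgt = int(rng.integers(0, 8))
            tr = make_centerout_trial(tgt, s_task).with_(
                rotation_deg=rotation_deg)
            trials.append(tr)
            seeds.append(s_init)
        return trials, seeds

    snapshots = {}
    history: list = []
    adam = _Adam(config)
    for epoch in range(n_epochs):
        if epoch in snapshot_epochs:
            snapshots[epoch] = params.W.copy()
        trials, seeds = gen(epoch)
        cache = run_batch(params, trials, seeds, feedback_on=False)
        loss, grads = loss_and_gradients(params, cache, config)
        if not np.isfinite(loss.total):
            raise RuntimeError(f"adaptation diverged at epoch {epoch}")
        _clip_global_norm(grads, ["W"], config.grad_clip_norm)
        adam.step(params, grads, ["W"])
        history.append({"epoch": epoch, "error_term": loss.error_term,
                        "total": loss.total})
    snapshots[n_epochs] = params.W.copy()
    return params, pd.DataFrame(history), snapshots
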