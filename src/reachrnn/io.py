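"""Configuration, serialisation and session storage.

Configs are TOML (key = value sections) validated against the default
hyperparameter set.  Network weights live in HDF5 containers with named
datasets (W, W_in, W_out, F, b, b_out, masks); sessions are written as a
tidy per-trial CSV log, an HDF5 time-series/snapshot container, a JSON
manifest that allows exact replay, and a provenance block (config hash,
seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .core import NetworkParams
from .plasticity import (AdaptationLog, PlasticityConfig, TrialRecord)
from .tasks import StimulationSpec, make_centerout_trial
from .training import TrainingConfig

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "save_weights",
    "load_weights",
    "write_session",
    "read_session",
]


@dataclass
class RunConfig:
    """Complete hyperparameter set (defaults = the published values)."""

    # architecture / dynamics (times in seconds)
    dt: float = 0.01
    tau: float = 0.05
    delta: float = 0.12
    n_units: int = 400
    phi: str = "relu"
    steps_per_trial: int = 300
    recurrent_prob: float = 1.0
    feedback_prob: float = 1.0
    # gradient descent
    alpha: float = 0.001
    batch_size: int = 20
    weight_reg: float = 0.001
    activity_reg: float = 0.002
    grad_clip_norm: float = 0.2
    epochs_block1: int = 100
    epochs_block2: int = 500
    epochs_block3: int = 500
    # feedback-driven plasticity (eta calibrated to this package's
    # trained networks; see PlasticityConfig)
    eta: float = 1e-3
    update_stride: int = 5
    # protocol
    rotation_deg: float = 30.0
    trials_baseline: int = 200
    trials_perturb: int = 500
    trials_washout: int = 200
    snapshot_every: int = 10
    # run
    seed: int = 0
    out_dir: str = "runs"

    def __post_init__(self):
        steps = self.delta / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"delta = {self.delta} s is not a multiple of dt = {self.dt} s")

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            alpha=self.alpha, batch_size=self.batch_size,
            weight_reg=self.weight_reg, activity_reg=self.activity_reg,
            grad_clip_norm=self.grad_clip_norm,
            epochs_per_block=(self.epochs_block1, self.epochs_block2,
                              self.epochs_block3),
            seed=self.seed)

    def plasticity_config(self) -> PlasticityConfig:
        return PlasticityConfig(eta=self.eta,
                                update_stride=self.update_stride)


def load_config(path) -> RunConfig:
    """Read and validate a TOML config; unknown keys are rejected and
    missing keys take the published defaults."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    flat = {}
    for key, val in raw.items():
        if isinstance(val, dict):   # allow [sections]; keys stay flat
            flat.update(val)
        else:
            flat[key] = val
    known = {f.name: f.type for f in fields(RunConfig)}
    unknown = set(flat) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, val in flat.items():
        default = getattr(RunConfig, key)
        if isinstance(default, bool) and not isinstance(val, bool):
            raise TypeError(f"config key {key}: expected bool, got {val!r}")
        if isinstance(default, (int, float)) and not isinstance(
                val, (int, float)):
            raise TypeError(f"config key {key}: expected number, got {val!r}")
        if isinstance(default, str) and not isinstance(val, str):
            raise TypeError(f"config key {key}: expected string, got {val!r}")
    return RunConfig(**flat)


def _toml_repr(val) -> str:
    if isinstance(val, bool):
        return "true" if val else "false"
    if isinstance(val, str):
        return json.dumps(val)
    return repr(val)


def save_config(config: RunConfig, path) -> None:
    lines = [f"{k} = {_toml_repr(v)}" for k, v in asdict(config).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# weights

def save_weights(params: NetworkParams, path) -> None:
    with h5py.File(path, "w") as fh:
        for nm in ("W", "W_in", "W_out", "F", "b", "b_out"):
            fh.create_dataset(nm, data=getattr(params, nm))
        for nm in ("recurrent_mask", "feedback_mask"):
            arr = getattr(params, nm)
            if arr is not None:
                fh.create_dataset(nm, data=arr)
        fh.attrs["dt"] = params.dt
        fh.attrs["tau"] = params.tau
        fh.attrs["delta"] = params.delta
        fh.attrs["phi"] = params.phi


def load_weights(path) -> NetworkParams:
    with h5py.File(path, "r") as fh:
        kw = {nm: fh[nm][()] for nm in
              ("W", "W_in", "W_out", "F", "b", "b_out")}
        for nm in ("recurrent_mask", "feedback_mask"):
            if nm in fh:
                kw[nm] = fh[nm][()]
        return NetworkParams(dt=float(fh.attrs["dt"]),
                             tau=float(fh.attrs["tau"]),
                             delta=float(fh.attrs["delta"]),
                             phi=str(fh.attrs["phi"]), **kw)


# --------------------------------------------------------------------------
# sessions

def _records_frame(log: AdaptationLog) -> pd.DataFrame:
    rows = []
    for rec in log.records:
        sp = rec.spec
        stim = sp.stimulation
        rows.append({
            "trial": rec.global_index, "phase": rec.phase,
            "phase_trial": rec.phase_index,
            "target_index": sp.target_index,
            "target_deg": sp.target_angle_deg,
            "go_time": sp.go_time,
            "rotation_deg": sp.rotation_deg,
            "error_clamp": sp.error_clamp,
            "stim_label": stim.label if stim else "",
            "stim_onset": stim.onset if stim else np.nan,
            "stim_duration": stim.duration if stim else np.nan,
            "stim_amplitude": stim.amplitude if stim else np.nan,
            "takeoff_angle_deg": rec.takeoff_angle_deg,
            "takeoff_error_deg": rec.takeoff_error_deg,
            "endpoint_error_cm": rec.endpoint_error_cm,
            "reaction_time_s": rec.reaction_time_s,
            "seed": rec.init_seed,
        })
    return pd.DataFrame(rows)


def write_session(log: AdaptationLog, out_dir,
                  config: Optional[RunConfig] = None,
                  phases: Optional[list] = None) -> Path:
    """Write trial CSV + HDF5 container + manifest + provenance JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _records_frame(log).to_csv(out / "trials.csv", index=False)

    with h5py.File(out / "series.h5", "w") as fh:
        snaps = fh.create_group("snapshots")
        for k, W in log.snapshots.items():
            snaps.create_dataset(str(k), data=W)
        if log.activity is not None:
            grp = fh.create_group("trials")
            for k in log.activity:
                g = grp.create_group(str(k))
                g.create_dataset("y", data=log.activity[k])
                g.create_dataset("v", data=log.velocity[k])
                g.attrs["trial"] = k
        if log.params_final is not None:
            final = fh.create_group("params_final")
            for nm in ("W", "W_in", "W_out", "F", "b", "b_out"):
                final.create_dataset(nm, data=getattr(log.params_final, nm))
            final.attrs["dt"] = log.params_final.dt
            final.attrs["tau"] = log.params_final.tau
            final.attrs["delta"] = log.params_final.delta
            final.attrs["phi"] = log.params_final.phi

    manifest = {
        "master_seed": log.master_seed,
        "n_trials": len(log.records),
        "phases": None if phases is None else [
            {"name": ph.name, "n_trials": ph.n_trials,
             "rotation_deg": ph.rotation_deg,
             "rotation_sd_deg": ph.rotation_sd_deg,
             "plasticity_on": ph.plasticity_on,
             "error_clamp": ph.error_clamp,
             "targets": list(ph.targets)}
            for ph in phases],
        "snapshot_trials": sorted(log.snapshots),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    prov = {"package_version": __version__,
            "seed": log.master_seed,
            "config_hash": config_hash(config) if config else None}
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    return out


def read_session(session_dir) -> AdaptationLog:
    """Rebuild an :class:`AdaptationLog` (scalar fields lossless) from a
    session directory; raises on missing components."""
    sdir = Path(session_dir)
    missing = [nm for nm in ("trials.csv", "series.h5", "manifest.json")
               if not (sdir / nm).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete session {sdir}: missing {missing}")
    df = pd.read_csv(sdir / "trials.csv")
    manifest = json.loads((sdir / "manifest.json").read_text())
    log = AdaptationLog(master_seed=int(manifest["master_seed"]))
    for row in df.itertuples():
        spec = make_centerout_trial(int(row.target_index), 0,
                                    go_time=float(row.go_time))
        spec = spec.with_(rotation_deg=float(row.rotation_deg),
                          error_clamp=bool(row.error_clamp))
        if isinstance(row.stim_label, str) and row.stim_label:
            spec = spec.with_(stimulation=StimulationSpec(
                label=row.stim_label, onset=float(row.stim_onset),
                duration=float(row.stim_duration),
                amplitude=float(row.stim_amplitude)))
        log.records.append(TrialRecord(
            global_index=int(row.trial), phase=str(row.phase),
            phase_index=int(row.phase_trial), spec=spec,
            init_seed=int(row.seed),
            takeoff_angle_deg=float(row.takeoff_angle_deg),
            takeoff_error_deg=float(row.takeoff_error_deg),
            endpoint_error_cm=float(row.endpoint_error_cm),
            reaction_time_s=float(row.reaction_time_s)))
    with h5py.File(sdir / "series.h5", "r") as fh:
        log.snapshots = {int(k): fh["snapshots"][k][()]
                         for k in fh["snapshots"]}
        if "trials" in fh:
            log.activity, log.velocity = {}, {}
            for k in fh["trials"]:
                log.activity[int(k)] = fh["trials"][k]["y"][()]
                log.velocity[int(k)] = fh["trials"][k]["v"][()]
        if "params_final" in fh:
            g = fh["params_final"]
            log.params_final = NetworkParams(
                W=g["W"][()], W_in=g["W_in"][()], W_out=g["W_out"][()],
                F=g["F"][()], b=g["b"][()], b_out=g["b_out"][()],
                dt=float(g.attrs["dt"]), tau=float(g.attrs["tau"]),
                delta=float(g.attrs["delta"]), phi=str(g.attrs["phi"]))
    return log
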