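"""Shared fixtures.

Training a competent closed-loop controller is the expensive step, so
trained networks are built once per session at a reduced scale (150
units, full three-block curriculum) and shared across behavioural and
population-analysis tests.
"""

import pytest

from reachrnn.analysis import DEFAULT_WINDOWS
from reachrnn.core import init_params
from reachrnn.experiments import vr_adaptation_session
from reachrnn.training import TrainingConfig, train_initial, train_no_feedback

N_UNITS = 150
CURRICULUM = (100, 500, 500)


@pytest.fixture(scope="session")
def tiny_params():
    return init_params(8, seed=2)


@pytest.fixture(scope="session")
def trained_net():
    cfg = TrainingConfig(epochs_per_block=CURRICULUM, seed=11)
    return train_initial(cfg, n_units=N_UNITS)


@pytest.fixture(scope="session")
def trained_net_b():
    cfg = TrainingConfig(epochs_per_block=CURRICULUM, seed=12)
    return train_initial(cfg, n_units=N_UNITS)


@pytest.fixture(scope="session")
def no_feedback_net():
    cfg = TrainingConfig(epochs_per_block=CURRICULUM, seed=4)
    return train_no_feedback(cfg, n_units=N_UNITS)


@pytest.fixture(scope="session")
def vr_session(trained_net):
    """30-deg rotation session: 60 baseline, 360 perturbation, 120
    washout trials, with window activity and epoch snapshots."""
    return vr_adaptation_session(
        trained_net, rotation_deg=30.0, counts=(60, 360, 120), seed=3,
        snapshot_every=0, record_windows=DEFAULT_WINDOWS)


@pytest.fixture(scope="session")
def vr_session_b(trained_net_b):
    return vr_adaptation_session(
        trained_net_b, rotation_deg=30.0, counts=(60, 360, 0), seed=7,
        snapshot_every=0, record_windows=DEFAULT_WINDOWS)
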