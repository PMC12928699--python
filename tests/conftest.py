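"""Shared fixtures: small synthetic epoch sets for fast module tests."""

import numpy as np
import pytest

from avdecode import SimConfig, make_eeg_schedule, simulate_epochs


#: scaled-down generative conditions used throughout the fast tests:
#: 8-16 sensors, 128 Hz, 400 ms epochs, 100-200 presentations/condition
SMALL_SIM = dict(
    n_participants=1,
    n_sensors=12,
    sample_rate_hz=128.0,
    epoch_window_s=(-0.05, 0.35),
)


@pytest.fixture(scope="session")
def small_epochs():
    """One participant, 3 conditions x 100 presentations, moderate SNR."""
    sched = make_eeg_schedule(
        n_participants=1, n_blocks=1, n_trials_per_block=10,
        n_presentations_per_trial=10, seed=11,
    )
    sim = SimConfig(noise_sigma=3.0, seed=11, **SMALL_SIM)
    epochs, truth = simulate_epochs(sched, sim)
    return epochs, truth


@pytest.fixture(scope="session")
def noiseless_epochs():
    """Noise-free tuned+evoked epochs: the exact-recovery regime."""
    sched = make_eeg_schedule(
        n_participants=1, n_blocks=1, n_trials_per_block=10,
        n_presentations_per_trial=5, seed=7,
    )
    sim = SimConfig(noise_sigma=0.0, seed=7, **SMALL_SIM)
    epochs, truth = simulate_epochs(sched, sim)
    return epochs, truth
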