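import numpy as np
import pandas as pd
import pytest

from popconf.data import SessionBundle
from popconf.synth import PopulationGenConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """Moderate synthetic session shared by unit tests (36 neurons)."""
    cfg = PopulationGenConfig(
        n_trials=1500, n_neurons_per_cluster=(12, 12, 12), seed=7
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def study_session():
    """Full-size synthetic session: 150 neurons, 4000 trials, fixed seed."""
    cfg = PopulationGenConfig(
        n_trials=4000, n_neurons_per_cluster=(50, 50, 50), seed=1
    )
    return generate_session(cfg)


def make_tiny_bundle():
    """Hand-built 2-trial, 3-neuron bundle with known spike counts."""
    trials = pd.DataFrame(
        {
            "trial_id": [0, 1],
            "coherence": [0.256, -0.128],
            "choice": ["left", "right"],
            "correct": [True, True],
            "rt": [0.6, 0.8],
            "session_id": ["s0", "s0"],
        }
    )
    spikes = pd.DataFrame(
        {
            "neuron_id": [0, 0, 0, 1, 1, 2, 0, 1],
            "trial_id":  [0, 0, 0, 0, 0, 0, 1, 1],
            "spike_time": [0.10, 0.20, 0.55, 0.05, 0.30, 0.45, 0.70, 0.25],
        }
    )
    neurons = pd.DataFrame(
        {
            "neuron_id": [0, 1, 2],
            "session_id": ["s0"] * 3,
            "neuron_class": ["Tin", "Tin", "Min_left"],
            "cluster": [np.nan] * 3,
        }
    )
    return SessionBundle(trials, spikes, neurons)


@pytest.fixture
def tiny_bundle():
    return make_tiny_bundle()
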