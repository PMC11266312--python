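import numpy as np
import pytest

from pulsesv import load_registry
from pulsesv.io import attach_subjects
from pulsesv.preprocessing import clean
from pulsesv.synthetic import ProtocolConfig, simulate_study


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_study():
    """One seeded synthetic study at modest size, shared across tests."""
    participants, obs, truth = simulate_study(
        seed=7, protocol=ProtocolConfig(beats_per_phase=60)
    )
    return participants, obs, truth


@pytest.fixture(scope="session")
def cleaned_study(small_study):
    participants, obs, _ = small_study
    merged = attach_subjects(obs, participants)
    cleaned, report = clean(merged)
    return participants, cleaned, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
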