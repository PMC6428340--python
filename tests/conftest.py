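import numpy as np
import pytest
from hypothesis import settings

import spikecal as sc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_dataset() -> sc.SyntheticDataset:
    """A default three-condition synthetic study shared across tests."""
    cfg = sc.SimulationConfig(n_transcripts=800, l_si=5.0e5)
    return sc.simulate_dataset(cfg, seed=20240917)


@pytest.fixture(scope="session")
def sim_calibration(sim_dataset):
    return sc.calibrate(sim_dataset.spikein_counts, sim_dataset.annotation)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
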