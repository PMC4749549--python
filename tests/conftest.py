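import numpy as np
import pytest

from caldrift.config import SimConfig
from caldrift.synthetic import generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default-regime synthetic experiment used by several test modules."""
    return generate_dataset(SimConfig(n_cells=150, seed=11))


@pytest.fixture(scope="session")
def default_cells(default_dataset):
    return list(range(default_dataset.config.n_cells))


@pytest.fixture(scope="session")
def trace_dataset():
    """Small dataset with rendered traces and footprints for detection tests."""
    cfg = SimConfig(n_cells=20, day_values=(1, 3), trials_per_session=2,
                    trial_duration=60.0, noise_sigma=0.02, amp_sigma=0.0,
                    place_cell_fraction=0.0, env_gain_sigma=0.0, seed=5)
    return generate_dataset(cfg, include_traces=True, include_footprints=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
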