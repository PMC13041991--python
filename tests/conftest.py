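import numpy as np
import pytest

from stackenc.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    config = SimulationConfig(
        n_subjects_per_group=3, n_grayordinates=24, n_parcels=6,
        n_timepoints=300, seed=11,
    )
    return simulate_study(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
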