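import warnings

import pytest
from hypothesis import HealthCheck, settings

import rosehip as rh

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_config() -> rh.SimulationConfig:
    """A reduced genome that keeps every structural feature of the default
    study conditions but runs in well under a second."""
    return rh.SimulationConfig(
        n_chromosomes=2,
        chromosome_length=4_500_000,
        chromosome_margin=100_000,
        n_clusters=5,
        n_singleton_peaks=40,
        n_loops=30,
        n_loops_pass=24,
        n_background_genes=20,
        n_proteins=60,
        n_interactors=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> rh.simulate.SimulatedDataset:
    return rh.simulate_dataset(small_config, seed=11)
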