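"""Shared fixtures: synthetic datasets at two scales.

The small dataset keeps every pipeline stage fast for unit tests; the
default-scale dataset is session-scoped and reused by the acceptance
checks that need realistic genome sizes.
"""

import pytest

from mitokit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_taxa=6, seed=7, length_scale=0.05)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimulationConfig(n_taxa=20, seed=1))
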