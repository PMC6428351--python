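from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from phosmod.simulate import SimParams, generate_scenario  # noqa: E402


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """A reduced scenario: quick to generate and run end-to-end."""
    return SimParams(
        n_kinases=2,
        substrates_per_kinase=15,
        n_decoy_peptides=60,
        n_network_nodes=150,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scenario(small_params):
    return generate_scenario(small_params)


@pytest.fixture(scope="session")
def noise_free_scenario():
    return generate_scenario(
        SimParams(
            n_kinases=2,
            substrates_per_kinase=12,
            n_decoy_peptides=40,
            n_network_nodes=120,
            noise_sd=0.0,
            seed=5,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
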