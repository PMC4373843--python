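import logging

import numpy as np
import pytest

from comethnet import (
    PlantedModule,
    SimulationConfig,
    simulate_cohort,
)

# keep expected-warning paths quiet in test output
logging.getLogger("comethnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """The standard study-sized cohort: 24 SP/SN pairs, 2000 probes,
    one planted module of 300 CpGs with acceleration ratio 14."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for unit tests: 12 pairs, 600 probes, module of 120."""
    cfg = SimulationConfig(
        seed=2, n_pairs=12, n_probes=600, modules=[PlantedModule(size=120)]
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def two_module_cohort():
    """Two planted modules with orthogonal latent factors plus background."""
    cfg = SimulationConfig(
        seed=2,
        n_probes=350,
        noise_sd=0.15,
        modules=[
            PlantedModule(size=100),
            PlantedModule(size=50, alpha_age=0.0, gamma_hiv=0.0),
        ],
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
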