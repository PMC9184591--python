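import numpy as np
import pytest

from cfbgwas import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def mediator_params() -> SimulationParams:
    """The mediator-effect null cell: genotype associated with baseline,
    baseline predictive of CFB, no direct genetic effect on CFB."""
    return SimulationParams(beta_G0=0.1, beta_y0=-0.2)


@pytest.fixture()
def small_cohort():
    return simulate_cohort(SimulationParams(n_subjects=20, maf=0.3, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
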