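import numpy as np
import pytest

from protraj import SimulationConfig, simulate_progression_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One small but fully structured cohort shared across tests."""
    config = SimulationConfig(
        n_normal=15,
        n_tumor_per_state={s: 25 for s in range(1, 8)},
        n_genes=300,
        n_informative=60,
        seed=11,
    )
    return simulate_progression_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
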