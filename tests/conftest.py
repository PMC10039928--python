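import numpy as np
import pytest

from gxeherit import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Modest LD-structured cohort with additive, GxE and exposure signal."""
    cfg = SimulationConfig(
        n_samples=500,
        n_variants=100,
        block_size=20,
        within_block_rho=0.5,
        h2_additive=0.2,
        h2_gxe=0.05,
        var_exposure_main=0.1,
        n_causal_additive=20,
        n_causal_gxe=10,
        n_covariates=2,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
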