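import numpy as np
import pytest

from tmtboot import SimulationConfig, simulate_cohort
from tmtboot.simulate import Effect


@pytest.fixture(scope="session")
def small_cohort():
    """Default-design cohort, 40 proteins, moderate noise."""
    return simulate_cohort(SimulationConfig(n_proteins=40), seed=101)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Zero-noise cohort with one planted effect at 15 min in cases."""
    cfg = SimulationConfig(
        n_proteins=12, subject_sd=0.0, residual_sd=0.0,
        effects=(Effect("PROT0001", "T15m", 1.0),),
    )
    return simulate_cohort(cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
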