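import numpy as np
import pytest

from meanbands.design import GROUPS
from meanbands.trial_synth import MissingnessParams, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_sim_config():
    """2 schools per arm, 40 students per cell: fast end-to-end material."""
    return SimConfig(
        n_schools_dm=2, n_schools_sc=2,
        group_sizes={g: 40 for g in GROUPS},
        seed=0,
    )


@pytest.fixture(scope="session")
def complete_sim_config():
    """Tiny trial with missingness switched off entirely."""
    return SimConfig(
        n_schools_dm=2, n_schools_sc=2,
        group_sizes={g: 30 for g in GROUPS},
        missingness=MissingnessParams.none(),
        seed=1,
    )
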