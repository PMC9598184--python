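import numpy as np
import pytest

from msfgait.features import table_from_trials
from msfgait.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def marker_trials():
    """Small noise-free marker-mode cohort for kinematics round trips."""
    cfg = CohortConfig(
        n_autism=2, n_control=2, marker_noise_sd=0.0, angle_noise_sd=0.0, seed=42
    )
    return simulate_cohort(cfg, mode="markers")


@pytest.fixture(scope="session")
def default_table():
    """Feature table of the default 19/21 angle-mode cohort."""
    return table_from_trials(simulate_cohort(CohortConfig(seed=7), mode="angles"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
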