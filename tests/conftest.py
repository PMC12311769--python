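import numpy as np
import pytest

from npbddm.ddm_core import canonical_bound, simulate_dataset
from npbddm.types import CoherencePrior, DDMParams, Grid


@pytest.fixture(scope="session")
def study_prior():
    return CoherencePrior.study_default()


@pytest.fixture(scope="session")
def truth_params():
    """The validation-study parameter triple."""
    return DDMParams(kappa=15.0, mu_nd=0.3, sigma_nd=0.01)


@pytest.fixture(scope="session")
def coarse_grid():
    return Grid.coarse(t_max=5.0)


@pytest.fixture(scope="session")
def three_level_prior():
    """A small prior (coh 0, +-3.2%) for fast solver tests."""
    return CoherencePrior(np.array([-0.032, 0.0, 0.032]), np.array([1, 1, 1]) / 3.0)


@pytest.fixture(scope="session")
def small_dataset(truth_params, study_prior):
    """200 trials per unit prior weight from a stationary bound."""
    return simulate_dataset(
        truth_params, canonical_bound("stationary"), 200, study_prior, seed=42
    )
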