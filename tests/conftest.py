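import numpy as np
import pytest

from tcrdyn.types import CohortParams, FluctParams, FormationParams


@pytest.fixture(scope="session")
def formation_params():
    """Small-scale formation parameters (gamma=0.1, d=0.2/yr)."""
    return FormationParams(b0=2e3, d=0.2, theta=2e2)


@pytest.fixture(scope="session")
def meanfield_validation_params():
    """Parameters at which the mean-field decoupling is validated
    against the exact coupled simulation."""
    return FormationParams(b0=2e4, d=0.2, theta=2e3)


@pytest.fixture(scope="session")
def cohort_params_scaled():
    """Simulated-cohort parameters with the recruitment rate scaled down
    10x for desk-scale runs; rank scales (r*) scale linearly with theta."""
    return CohortParams(theta=1e4)


@pytest.fixture(scope="session")
def fluct_params():
    """Fluctuating-selection parameters of the simulated cohort
    (sigma2=0.08/yr, drift set to -alpha*sigma2 with alpha=1.1)."""
    return FluctParams(f0=-1.1 * 0.08, sigma2=0.08)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
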