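import numpy as np
import pytest

from tnedose.quantification import RCModel
from tnedose.synthetic import CohortConfig, median_kinetics

GRID = np.array([2.0, 24.0, 48.0, 168.0])


@pytest.fixture(scope="session")
def grid():
    return GRID


@pytest.fixture(scope="session")
def zero_noise_config():
    return CohortConfig(noise_cv=0.0)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig()


@pytest.fixture(scope="session")
def rc_truth():
    return RCModel(a=15.0, b=2.5)


@pytest.fixture(scope="session")
def median_fits(default_config):
    """Fits at the cohort-median kinetics for all three tissues."""
    return {
        tissue: k.as_fit()
        for tissue, k in median_kinetics(default_config).items()
    }


def random_valid_fit(rng: np.random.Generator):
    """A random biexponential curve satisfying the fit invariants."""
    from tnedose.dose_rate import BiexpFit

    a = -float(rng.uniform(0.001, 0.05))
    b = a - float(rng.uniform(0.01, 0.5))
    c1 = float(rng.uniform(0.001, 1.0))
    if rng.random() < 0.5:  # uptake shape
        c2 = -c1 * float(rng.uniform(0.1, 1.0))
    else:  # washout shape
        c2 = float(rng.uniform(0.0, 1.0))
    return BiexpFit(C1=c1, C2=c2, a=a, b=b)
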