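import numpy as np
import pytest

import ramclav as rc


@pytest.fixture(scope="session")
def default_spec():
    return rc.default_cohort_spec(seed=1)


@pytest.fixture(scope="session")
def cohort(default_spec):
    return rc.simulate_cohort(default_spec)


@pytest.fixture(scope="session")
def processed(cohort):
    return rc.preprocess_set(cohort)


@pytest.fixture(scope="session")
def metrics_table(processed):
    return rc.cohort_metrics(processed)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def gaussian_band(center=960.0, sigma=5.0, amplitude=1.0,
                  lo=594.0, hi=1704.0, meta=None):
    """A single pure-Gaussian band on the standard 1 cm^-1 grid."""
    x = np.arange(lo, hi + 1.0)
    y = amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return rc.RamanSpectrum(x, y, meta)


def lorentzian_band(center=960.0, gamma=6.0, amplitude=1.0,
                    lo=594.0, hi=1704.0):
    x = np.arange(lo, hi + 1.0)
    y = amplitude / (1.0 + ((x - center) / gamma) ** 2)
    return rc.RamanSpectrum(x, y)
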