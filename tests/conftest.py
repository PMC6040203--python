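import numpy as np
import pytest
from hypothesis import settings

from dsbayes import (
    ConjugateFamily,
    DSPrior,
    fit_mle,
    jeffreys,
    load_dataset,
    mom2_fit,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rat_data():
    return load_dataset("rat_tumor")


@pytest.fixture(scope="session")
def navy_data():
    return load_dataset("navy_shipyard")


@pytest.fixture(scope="session")
def insurance_data():
    return load_dataset("insurance_counts")


@pytest.fixture(scope="session")
def rat_family(rat_data):
    return fit_mle(rat_data, "binomial")


@pytest.fixture(scope="session")
def insurance_family(insurance_data):
    return fit_mle(insurance_data, "poisson")


@pytest.fixture(scope="session")
def rat_fit(rat_data, rat_family):
    return mom2_fit(rat_data, rat_family)


@pytest.fixture(scope="session")
def navy_fit(navy_data):
    return mom2_fit(navy_data, jeffreys())


@pytest.fixture(scope="session")
def insurance_fit(insurance_data, insurance_family):
    return mom2_fit(insurance_data, insurance_family)


@pytest.fixture(scope="session")
def rat_printed_prior():
    """The published bimodal rat-tumor prior: Beta(2.30, 14.08) with a
    single third-order correction of -0.50."""
    return DSPrior(ConjugateFamily("binomial", 2.30, 14.08), [0.0, 0.0, -0.50])


@pytest.fixture
def rng():
    return np.random.default_rng(1)
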