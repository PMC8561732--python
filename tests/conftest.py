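import numpy as np
import pytest

from microer import conditions
from microer.tls import fit_echt, fit_ptls


@pytest.fixture(scope="session")
def toy_model():
    return conditions.standard_structure()


@pytest.fixture(scope="session")
def standard_fixture():
    """Heterogeneous-disorder toy crystal under the standard conditions."""
    return conditions.standard_fixture(seed=1)


@pytest.fixture(scope="session")
def echt_model(standard_fixture):
    return fit_echt(standard_fixture.mean_model)


@pytest.fixture(scope="session")
def ptls_model(standard_fixture):
    return fit_ptls(standard_fixture.mean_model, ptls_fraction=0.9)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
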