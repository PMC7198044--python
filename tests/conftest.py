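import numpy as np
import pytest

from ihcquant import default_hdab_matrix, default_step_tablet


@pytest.fixture(scope="session")
def basis():
    return default_hdab_matrix()


@pytest.fixture(scope="session")
def tablet():
    return default_step_tablet()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230917)
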