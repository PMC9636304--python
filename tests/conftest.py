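import numpy as np
import pytest

from irthresh import make_response_function


@pytest.fixture(scope="session")
def normal_rf():
    return make_response_function("normal")


@pytest.fixture(scope="session")
def logistic_rf():
    return make_response_function("logistic")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
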