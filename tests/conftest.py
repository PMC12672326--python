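import pytest

from pcsk9cua import base_case, evaluate_all, make_test_parameters

EVO = "Evolocumab 140 mg Q2W"
STATINS = "Statins alone"


@pytest.fixture(scope="session")
def base_params():
    return base_case()


@pytest.fixture(scope="session")
def base_outcomes(base_params):
    return evaluate_all(base_params)


@pytest.fixture(scope="session")
def degenerate_params():
    return make_test_parameters(difficulty="degenerate")


@pytest.fixture()
def simple_params():
    return make_test_parameters(seed=3, difficulty="simple")
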