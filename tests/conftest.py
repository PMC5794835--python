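import numpy as np
import pytest

from granulosim import (
    GcsfSchedule,
    make_reference_params,
    make_toy_regimen,
    simulate,
)


@pytest.fixture(scope="session")
def ref_params():
    return make_reference_params()


@pytest.fixture(scope="session")
def chop14():
    return make_toy_regimen("chop14_like")


@pytest.fixture(scope="session")
def single_drug():
    return make_toy_regimen("single_drug")


@pytest.fixture(scope="session")
def fil_d4_13():
    return GcsfSchedule.consecutive("filgrastim", 4, 10, 300.0)


@pytest.fixture(scope="session")
def chop14_no_gcsf_result(ref_params, chop14):
    """One CHOP-14-like simulation without G-CSF, shared across tests."""
    return simulate(ref_params, chop14)


@pytest.fixture(scope="session")
def chop14_fil_result(ref_params, chop14, fil_d4_13):
    return simulate(ref_params, chop14, fil_d4_13)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
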