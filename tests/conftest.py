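import numpy as np
import pytest

from gapcircuit.bcd_profiles import BcdExponential
from gapcircuit.core_model import MitosisSchedule
from gapcircuit.synthetic_data import (
    gen_external_inputs,
    gen_maternal_hb,
    gen_parameter_fixture,
)


@pytest.fixture(scope="session")
def schedule():
    return MitosisSchedule()


@pytest.fixture(scope="session")
def bistable_params():
    return gen_parameter_fixture("bistable_border")


@pytest.fixture(scope="session")
def monostable_params():
    return gen_parameter_fixture("monostable")


@pytest.fixture(scope="session")
def decoupled_params():
    return gen_parameter_fixture("decoupled")


@pytest.fixture(scope="session")
def external_inputs(schedule):
    return gen_external_inputs(schedule)


@pytest.fixture(scope="session")
def cad_table(external_inputs):
    return external_inputs[0]


@pytest.fixture(scope="session")
def tll_table(external_inputs):
    return external_inputs[1]


@pytest.fixture(scope="session")
def hb0():
    return gen_maternal_hb()


@pytest.fixture(scope="session")
def median_profile():
    # amplitude/decay of a typical synthetic median embryo
    return BcdExponential(200.0, 1.0 / 15.0, "median")
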