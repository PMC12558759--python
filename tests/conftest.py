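import numpy as np
import pytest

from matrine_pbpk import DoseRegimen, optimized_parameters, starting_parameters
from matrine_pbpk.schedules import EXPERIMENT_1_SCHEDULE_H


@pytest.fixture(scope="session")
def opt_params():
    """Fitted parameter set at the single-dose study mid-range weight."""
    return optimized_parameters(BW=27.0)


@pytest.fixture(scope="session")
def gen_params():
    """Generator parameterization (dose-scaled bioavailability)."""
    return optimized_parameters(BW=27.0, f_mode="dose_scale")


@pytest.fixture(scope="session")
def start_params():
    return starting_parameters(BW=27.0)


@pytest.fixture(scope="session")
def regimen40():
    return DoseRegimen.single_oral(40.0, 27.0)


@pytest.fixture(scope="session")
def exp1_grid():
    return EXPERIMENT_1_SCHEDULE_H.copy()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
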