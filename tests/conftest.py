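import warnings

import numpy as np
import pytest

from levandmm.kinetic_core import KineticParameterSet
from levandmm.presets import PRESETS
from levandmm.simulator import SimulationConfig
from levandmm.synthetic_data import generate_toy_gem

# cobra emits deprecation chatter on import in some environments
warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def low_params():
    return PRESETS["low"]


@pytest.fixture(scope="session")
def high_params():
    return PRESETS["high"]


@pytest.fixture(scope="session")
def transition_params():
    return PRESETS["transition"]


@pytest.fixture(scope="session")
def simple_params():
    """Round numbers so rate-law values can be checked by hand."""
    return KineticParameterSet(
        mu_max=0.2, Ks=10.0, kd=0.01, Y_XS=0.05, alpha=20.0,
        vmax_hyd=2.0, KM_hyd=10.0,
        vmax_trans1=4.0, KM_trans1=100.0, vmax_trans2=4.0, KM_trans2=1000.0,
        vmax_levdeg=0.5, KM_levdeg=20.0, t_levdeg_onset=12.0,
    )


@pytest.fixture(scope="session")
def toy_gem():
    return generate_toy_gem()


@pytest.fixture(scope="session")
def toy_gem_bare():
    """Toy network without the levansucrase pseudo-reaction."""
    return generate_toy_gem(include_levansucrase=False)


@pytest.fixture
def short_cfg():
    return SimulationConfig(initial_sucrose=100.0, horizon=30.0,
                            report_grid=tuple(np.arange(0.0, 30.01, 3.0)))
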