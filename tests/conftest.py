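import numpy as np
import pytest

from canopyflux.chamber import SystemConfig
from canopyflux.leaf import Environment, LeafParams
from canopyflux.structure import CanopyState
from canopyflux.synthetic import SyntheticScenario, generate_weather


@pytest.fixture(scope="session")
def system_config():
    return SystemConfig()


@pytest.fixture(scope="session")
def leaf_params():
    """Shipped default leaf parameterization."""
    return LeafParams()


@pytest.fixture(scope="session")
def canopy():
    """Mid-size fertilized container canopy."""
    return CanopyState(lai=2.2, sln0=1.3, kn=0.35)


@pytest.fixture(scope="session")
def midday_env():
    return Environment(par=1800.0, t_air=30.0, co2=400.0, vp=2.2, sin_beta=0.9)


@pytest.fixture(scope="session")
def weather_day():
    """One clear diurnal cycle at 12-min cadence, seeded."""
    return generate_weather(SyntheticScenario(random_seed=11))


@pytest.fixture(scope="session")
def weather_day_coarse():
    """Half-hour cadence weather for slower model-in-the-loop tests."""
    return generate_weather(SyntheticScenario(random_seed=11), cadence_s=1800)
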