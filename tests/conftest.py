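import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mroximetry import AcquisitionSchedule, KineticConstants
from mroximetry.territories import VeinTerritoryAtlas

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    return AcquisitionSchedule.default()


@pytest.fixture(scope="session")
def constants():
    return KineticConstants.for_hct(0.42)


@pytest.fixture(scope="session")
def atlas():
    return VeinTerritoryAtlas.default()


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)
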