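import pytest
from hypothesis import HealthCheck, settings

from capsar import AnalogParams, DacConfig, SensorConfig, realize

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def nominal_real():
    """Nominal (mismatch-free) default 4+8-bit DAC bank."""
    return realize(DacConfig())


@pytest.fixture(scope="session")
def ideal_params():
    """Offset-free, noise-free converter parameters."""
    return AnalogParams.ideal()


@pytest.fixture(scope="session")
def sensor_cfg():
    return SensorConfig()
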