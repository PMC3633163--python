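import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from saccsim import ModelParameters

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    """Reference parameter set (weak drive: g=0.15, A=50)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def strong_params():
    """Strong-drive configuration used for the saturation experiments."""
    return ModelParameters(g=0.2, A=100.0)
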