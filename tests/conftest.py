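import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitrain import TimingScheme, standard_montage

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def timing():
    return TimingScheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
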