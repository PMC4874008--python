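import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xlexhaust.config import SearchConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def config() -> SearchConfig:
    return SearchConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
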