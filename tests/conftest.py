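import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def grid200():
    from cxclgrad import build_grid

    return build_grid(200.0, 10.0)


@pytest.fixture()
def grid100():
    from cxclgrad import build_grid

    return build_grid(100.0, 10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
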