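import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def screen_truth():
    from sarcoscreen.simulate import ScreenTruth

    return ScreenTruth("drugA", ic50=1.0, hill=1.0, top=1.0, bottom=0.0)
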