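import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# one deterministic profile for the whole suite
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20140911)


@pytest.fixture
def tiny_table():
    """L=2 binary landscape used by the worked approximation examples."""
    from peakwalk import SequenceSpace, TabulatedLandscape

    space = SequenceSpace(2, "01")
    return TabulatedLandscape(space, {"00": 5.0, "01": 1.0, "10": 2.0, "11": 3.0})
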