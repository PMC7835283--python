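import numpy as np
import pytest

from seegnet import H2Config, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_h2():
    """h² config without lag scanning, for tests that don't need it."""
    return H2Config(lag_range_ms=(0.0, 0.0))


@pytest.fixture
def two_channel_recording(rng):
    return Recording(["A", "B"], 200.0, rng.normal(0.0, 40.0, size=(2, 2000)))
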