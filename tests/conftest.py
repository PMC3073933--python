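import numpy as np
import pytest

from chemofield import FrameSeries, PointField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series(rng) -> FrameSeries:
    """Three 2-D frames of 40 random points each, strictly increasing times."""
    fields = [PointField(rng.uniform(0, 1, size=(40, 2))) for _ in range(3)]
    return FrameSeries([0.0, 1.0, 2.0], fields)
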