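import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def circle_sdf():
    """Signed distance to a radius-20 circle on a 128x128 grid (inside < 0)."""
    rr, cc = np.mgrid[0:128, 0:128]
    return np.hypot(rr - 64.0, cc - 64.0) - 20.0
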