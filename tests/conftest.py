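import numpy as np
import pytest

from pfr.channels import ChannelSeries
from pfr.synthetic import SyntheticSpec, generate_regime_epoch


@pytest.fixture(scope="session")
def ppfr_epoch():
    """One clean positively coordinated 2-h epoch (generated, not stored)."""
    return generate_regime_epoch(SyntheticSpec.for_regime("pPFR", seed=11))


@pytest.fixture(scope="session")
def npfr_epoch():
    return generate_regime_epoch(SyntheticSpec.for_regime("nPFR", seed=12))


@pytest.fixture
def minute_cpp():
    """A structured 1-min CPP series for inversion tests."""
    rng = np.random.default_rng(7)
    n = 120
    t = np.arange(n) * 60.0
    v = (80.0 + 5 * np.sin(2 * np.pi * t / 600)
         + 3 * np.sin(2 * np.pi * t / 1700 + 1.0)
         + 0.1 * rng.normal(0, 1, n).cumsum())
    return ChannelSeries("CPP", t, v, "mmHg", 1 / 60)
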