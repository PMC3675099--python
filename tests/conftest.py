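import numpy as np
import pytest

from pprcode.training import ORGANELLAR_BACKGROUND


@pytest.fixture
def bg():
    """Pooled organellar background (the shipped totals)."""
    return ORGANELLAR_BACKGROUND


@pytest.fixture
def rng():
    return np.random.default_rng(0)
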