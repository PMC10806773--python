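import numpy as np
import pytest

from idplink.datatypes import SAXSProfile
from idplink.synth import debye_profile


@pytest.fixture
def debye4() -> SAXSProfile:
    """Noiseless ideal-chain curve, Rg = 4 nm, I0 = 100, dense low-q grid."""
    q = np.geomspace(0.02, 2.0, 200)
    return debye_profile(4.0, 100.0, q)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
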