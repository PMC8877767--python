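import numpy as np
import pytest

from vegsize.geometry import INTRINSICS_PROFILES


@pytest.fixture(scope="session")
def cam():
    """RealSense D415 RGB intrinsics at VGA, the default working profile."""
    return INTRINSICS_PROFILES["d415-vga"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
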