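import numpy as np
import pytest

from gazelab.geometry import ScreenGeometry


@pytest.fixture
def geom24() -> ScreenGeometry:
    """24-inch 16:9 screen (531.3 x 298.9 mm, 1920x1080) viewed at 800 mm."""
    return ScreenGeometry(531.3, 298.9, 1920, 1080, 800.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160711)
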