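import numpy as np
import pytest

from leafpeel import ImageStack


@pytest.fixture
def step_stack() -> ImageStack:
    """Noiseless marker: 0 above z=5, 100 from z=5 down, every column."""
    vox = np.zeros((1, 10, 8, 8), dtype=np.float32)
    vox[0, 5:] = 100.0
    return ImageStack(vox, ["membrane"], (1.0, 1.0, 1.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
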