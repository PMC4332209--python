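import numpy as np
import pytest

from thromboflux import AssayDesign


@pytest.fixture
def noiseless_design() -> AssayDesign:
    """Reference acquisition: 35-s frames over 600 s, no camera noise."""
    return AssayDesign(noise_sd=0.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
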