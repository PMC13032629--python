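import numpy as np
import pytest

from mhri import synthetic_oct as so


@pytest.fixture(scope="session")
def clean_phantom():
    """Default noise-free phantom (MLD 300 µm, 10 µm/px laterally)."""
    return so.generate_bscan(so.PhantomConfig(speckle_level=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
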