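import numpy as np
import pytest

from ezoct.phantom import PhantomSpec, compact_spec, generate_bscan


@pytest.fixture(scope="session")
def clean_spec():
    """Full-size noise-free phantom spec (Spectralis-like geometry)."""
    return PhantomSpec(speckle_level=0.0)


@pytest.fixture(scope="session")
def clean_pair(clean_spec):
    """Noise-free full-size phantom with exact ground truth."""
    return generate_bscan(clean_spec, seed=7)


@pytest.fixture(scope="session")
def compact_noisy_pair():
    """Small speckled phantom for fast end-to-end checks."""
    spec = compact_spec(96, 96, speckle_level=0.2)
    return generate_bscan(spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
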