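import numpy as np
import pytest

from ipsonn import PhantomSpec, generate_phantom, skull_strip


@pytest.fixture(scope="session")
def tumor_phantom():
    """Noise-free slice with a tumor disc and edema halo."""
    spec = PhantomSpec(noise_sd=0.0, seed=11,
                       tumor=((85.0, 105.0), 12.0), edema_halo_width=6.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def normal_phantom():
    """Noise-free slice without pathology."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=12))


@pytest.fixture(scope="session")
def stripped_tumor(tumor_phantom):
    return skull_strip(tumor_phantom.intensity)


@pytest.fixture(scope="session")
def stripped_normal(normal_phantom):
    return skull_strip(normal_phantom.intensity)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
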