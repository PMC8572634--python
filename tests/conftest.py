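import numpy as np
import pytest

from cowseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free default phantom: geometry checks need exact HU."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, bias_field_amplitude=0.0,
                                        seed=11))


@pytest.fixture(scope="session")
def default_phantom():
    """Default phantom with noise and bias field."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
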