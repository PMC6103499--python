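import numpy as np
import pytest

from spixcrf import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(noise_sigma=0.0, bias_amplitude=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_spec():
    return PhantomSpec(noise_sigma=0.05, bias_amplitude=0.10, seed=0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def noisy_phantom(noisy_spec):
    return generate_phantom(noisy_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
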