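import numpy as np
import pytest

from ctneoquant.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, artifact-free 64^3 construct with ground truth."""
    return generate_phantom(PhantomSpec(shape=(64, 64, 64)))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Mildly degraded 64^3 construct (blur + noise), fixed seed."""
    spec = PhantomSpec(shape=(64, 64, 64), psf_sigma_vox=0.5,
                       noise_sigma=3.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
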