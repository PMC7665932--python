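import numpy as np
import pytest

from mrdenoise.phantom import ImagePair, NoiseSpec, add_noise, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def pair_64():
    """A 64x64 phantom corrupted with 7% Rician noise."""
    clean = generate_phantom(64, 64, n_shapes=5, seed=7)
    return add_noise(clean, NoiseSpec(model="rician", percent=7.0, seed=11))


@pytest.fixture
def random_pair(rng):
    """A random-valued 48x48 pair (no phantom structure)."""
    clean = rng.random((48, 48))
    noisy = clean + rng.normal(0, 0.05, clean.shape)
    return ImagePair(clean=clean, noisy=noisy, noise=NoiseSpec(model="gaussian", percent=5.0))
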