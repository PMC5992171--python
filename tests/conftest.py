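import numpy as np
import pytest

from octlumen.phantom import PhantomSpec, cylinder, generate_phantom


@pytest.fixture(scope="session")
def small_noisy_phantom():
    """20-frame noisy cylinder pullback (r = 1.2 mm) with ground truth."""
    spec = PhantomSpec(
        n_frames=20,
        lumen_radius_fn=cylinder(1.2),
        speckle_shape=4.0,
        background_noise_sd=0.02,
        seed=1,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_clean_phantom():
    """10-frame noise-free cylinder pullback (r = 1.0 mm) with ground truth."""
    spec = PhantomSpec(n_frames=10, lumen_radius_fn=cylinder(1.0), seed=0)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
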