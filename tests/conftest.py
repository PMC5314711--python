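import numpy as np
import pytest

from cinestrain.phantom import PhantomSpec, generate_lax_phantom, generate_sax_phantom
from cinestrain.registration import RegistrationParams


@pytest.fixture(scope="session")
def small_sax():
    """Small contracting SAX phantom for registration tests."""
    spec = PhantomSpec(grid_size=96, n_frames=6, es_frame=3, seed=5)
    return spec, *generate_sax_phantom(spec)


@pytest.fixture(scope="session")
def small_sax_clean():
    """Noise-free small SAX phantom (exact advection checks)."""
    spec = PhantomSpec(grid_size=96, n_frames=6, es_frame=3, noise_sd=0.0, seed=5)
    return spec, *generate_sax_phantom(spec)


@pytest.fixture(scope="session")
def small_lax():
    spec = PhantomSpec(view="LAX", grid_size=96, n_frames=6, es_frame=3, seed=5)
    return spec, *generate_lax_phantom(spec)


@pytest.fixture()
def fast_params():
    return RegistrationParams(pyramid_levels=2, max_iterations=60)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
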