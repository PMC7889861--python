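import numpy as np
import pytest

from cmbdetect.config import CutoffConfig
from cmbdetect.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def config():
    return CutoffConfig()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with three spheres (deterministic)."""
    spec = PhantomSpec(
        n_spheres=3,
        sphere_radius_mm=(0.75, 1.65),
        noise_sigma=0.0,
        seed=42,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise phantom with two spheres (deterministic)."""
    spec = PhantomSpec(n_spheres=2, sphere_radius_mm=(0.75, 1.65), seed=7)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
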