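import numpy as np
import pytest

from tenoquant.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Desk-size wrist phantom: 40 mm field at 0.8 mm, one inflamed flexor."""
    return PhantomSpec.default(
        field_mm=40.0,
        spacing_mm=0.8,
        sheath_thickness={"flexor_3": 3.0},
        seed=1,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free, inflammation-free phantom for geometry-exact checks."""
    spec = PhantomSpec.default(field_mm=40.0, spacing_mm=0.8, noise_sd=0.0, seed=2)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
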