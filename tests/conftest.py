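import numpy as np
import pytest

from munet.data import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A small phantom case with all three tumor tissues present."""
    spec = PhantomSpec(
        shape=(64, 64, 8),
        num_lesions=1,
        enhancing_radius=(3, 5),
        core_radius=(6, 9),
        edema_radius=(10, 14),
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_spec():
    return PhantomSpec(
        shape=(64, 64, 8),
        num_lesions=1,
        enhancing_radius=(3, 5),
        core_radius=(6, 9),
        edema_radius=(10, 14),
        seed=7,
    )
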