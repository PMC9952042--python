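import numpy as np
import pytest

from sbbdem.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benign_phantom():
    return generate_phantom(PhantomSpec(seed=11, acr_level=3, mass_kinds=("benign",), n_masses=1))


@pytest.fixture(scope="session")
def malignant_phantom():
    return generate_phantom(PhantomSpec(seed=12, acr_level=3, mass_kinds=("malignant",), n_masses=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Fixed mixed cohort reused by read-only tests."""
    return [
        generate_phantom(PhantomSpec(seed=500 + i, acr_level=1 + i % 4))
        for i in range(8)
    ]
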