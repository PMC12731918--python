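import numpy as np
import pytest

from adipoquant.phantom import PhantomSpec, generate_phantom
from adipoquant.roi_core import BinaryMask3D


@pytest.fixture(scope="session")
def clean_phantom():
    """Default-size phantom without intensity noise (exact-recovery oracle)."""
    return generate_phantom(PhantomSpec(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_phantom():
    """Tiny phantom for fast structural tests."""
    return generate_phantom(
        PhantomSpec(dims=(8, 64, 64), sat_thickness=5.0, slice_margin=2, seed=3, noise_sd=0.0)
    )


def make_mask(data, spacing=(1.0, 1.0, 1.0), label=""):
    return BinaryMask3D(np.asarray(data, dtype=bool), spacing, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
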