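import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spimkit.phantoms import gen_bead_stack, gen_tls_pair, gen_vessel_drug_masks
from spimkit.stacks import ImageStack


@pytest.fixture(scope="session")
def bead_stack():
    """One seeded fine-axial bead phantom with its truth manifest."""
    return gen_bead_stack(seed=11)


@pytest.fixture(scope="session")
def tls_pair():
    """One seeded pair of focus-shifted nuclei stacks."""
    return gen_tls_pair(seed=3)


@pytest.fixture(scope="session")
def vessel_drug():
    """One seeded vessel/drug mask pair with uniform halo radius."""
    return gen_vessel_drug_masks(seed=5)


@pytest.fixture
def random_stack():
    """Small random 8-bit stack for bit-exactness and metric checks."""
    rng = np.random.default_rng(42)
    return ImageStack(rng.integers(0, 256, size=(6, 16, 20), dtype=np.uint8), (10.0, 3.45, 3.45))
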