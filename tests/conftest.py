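import numpy as np
import pytest

from cellmorph.phantom import PhantomSpec, generate_phantom
from cellmorph.volume import LabeledVolume


@pytest.fixture(scope="session")
def small_phantom():
    """Four bilateral pairs, mixed contact; reused read-only across tests."""
    return generate_phantom(PhantomSpec(n_cell_pairs=4, seed=7))


@pytest.fixture(scope="session")
def small_volume(small_phantom):
    return LabeledVolume.from_phantom(small_phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
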