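import numpy as np
import pytest

from hdlamyloid import synth
from hdlamyloid.datatypes import HeightMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def ideal_fibril():
    """Perfect axis-aligned cross-β pentamer (residues 17-42, rise 0.48 nm)."""
    return synth.gen_ideal_fibril(synth.IdealFibrilSpec())


@pytest.fixture
def random_fibril_factory():
    """Random 5-chain × 26-residue coordinate systems for oracle checks."""
    def make(seed):
        r = np.random.default_rng(seed)
        from hdlamyloid.datatypes import FibrilCoordinates
        coords = r.normal(0, 1.0, size=(5, 26, 3))
        return FibrilCoordinates(list("ABCDE"), coords, np.arange(17, 43))
    return make


@pytest.fixture
def flat_map():
    return HeightMap(np.zeros((40, 40)), pixel_size=2.0)
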