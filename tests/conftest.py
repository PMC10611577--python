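import numpy as np
import pytest

from mbnf import localizer as loc
from mbnf import synth

GRID = (20, 20, 10)


@pytest.fixture(scope="session")
def planted_maps():
    """Two disjoint network loading fields on the standard toy grid."""
    return synth.make_network_maps(GRID, 2, 3, seed=7)


@pytest.fixture(scope="session")
def planted_masks(planted_maps):
    """Top-10% binarized masks of the planted DMN/CEN fields."""
    dmn = loc.threshold_and_binarize(planted_maps[0], top_fraction=0.10,
                                     network_label="DMN").binary_field
    cen = loc.threshold_and_binarize(planted_maps[1], top_fraction=0.10,
                                     network_label="CEN").binary_field
    return dmn, cen


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
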