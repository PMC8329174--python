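import numpy as np
import pytest

from ionoscopy import synthetic


@pytest.fixture(scope="session")
def small_geometry():
    """A 256x256 cell at 20 nm/pixel shared by read-only tests."""
    return synthetic.make_cell_geometry((256, 256), 20.0, seed=11)


@pytest.fixture(scope="session")
def synthetic_cell_scene():
    """Medium synthetic cell: geometry, placement and rendered pair."""
    geom = synthetic.make_cell_geometry((512, 512), 20.0, seed=21)
    sizes = synthetic.SizeDistribution("lognormal", 35.0, 0.2)
    placement = synthetic.place_nanodiamonds(geom, 120, sizes,
                                             min_nucleus_gap_nm=457.0, seed=22)
    pair = synthetic.render_correlative_pair(placement, geom, seed=23)
    return geom, placement, pair


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
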