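import numpy as np
import pytest

from icemono import synthetic_data as sd
from icemono import order_params as op


@pytest.fixture(scope="session")
def ic222():
    return sd.build_ice_lattice("Ic", (2, 2, 2))


@pytest.fixture(scope="session")
def ih432():
    # ≥4 cells along x so no primitive 6-cycle can wind around the box
    return sd.build_ice_lattice("Ih", (4, 3, 2))


@pytest.fixture(scope="session")
def liquid_slab_small():
    return sd.build_liquid_slab(360, np.array([22.0, 22.0, 22.0]), min_dist=2.45, seed=1)


@pytest.fixture(scope="session")
def ic_graph(ic222):
    return op.neighbor_list(ic222, 3.2, method="brute")


@pytest.fixture(scope="session")
def ih_graph(ih432):
    return op.neighbor_list(ih432, 3.2, method="brute")


def random_cluster_config(rng, n=60, radius=8.0):
    """Non-periodic blob of points for rotation-invariance checks."""
    from icemono.trajectory_io import Configuration

    pts = rng.normal(0, radius / 2, (n, 3))
    pts -= pts.min(axis=0) - 5.0
    box = pts.max(axis=0) + 5.0
    return Configuration(np.array(["OW"] * n, dtype=object), np.arange(n), pts,
                         box, (False, False, False))
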