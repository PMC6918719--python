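import numpy as np
import pytest
from shapely.geometry import Point

from routescape.synthetic import RouteEdge, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disc_hr():
    """A ~10 ha circular home range."""
    return Point(300.0, 300.0).buffer(178.4, quad_segs=64)


@pytest.fixture
def small_config():
    return SyntheticConfig(seed=7, n_groups=2, extent=(0, 0, 700, 400),
                           n_weeks=6, n_trees=100, route_nodes=8)


def separated_edges(seed, multiplicities=(1, 2, 4, 7)):
    """Planted route segments far enough apart that junction effects
    cannot confound a noise-recovery measurement."""
    rg = np.random.default_rng(seed)
    edges = []
    for i, m in enumerate(multiplicities):
        y = 60.0 + i * 70.0
        xs = np.linspace(40.0, 290.0, 6)
        ys = y + np.cumsum(rg.normal(0.0, 4.0, 6))
        edges.append(RouteEdge(np.column_stack([xs, ys]), m))
    return edges
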