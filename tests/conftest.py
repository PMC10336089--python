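import numpy as np
import pytest

from pdirac import SimplicialComplex, rips_filtration


@pytest.fixture
def triangle():
    """A single filled triangle."""
    return SimplicialComplex([(0, 1, 2)])


@pytest.fixture
def tetrahedron():
    """A single filled tetrahedron."""
    return SimplicialComplex([(0, 1, 2, 3)])


@pytest.fixture
def four_cycle():
    """The boundary of a square: 4 vertices, 4 edges, no triangles."""
    return SimplicialComplex([(0, 1), (1, 2), (2, 3), (0, 3)])


def random_rips(seed: int, n: int = 8, max_dim: int = 3, radius: float = 1.2):
    """A Rips filtration of a seeded uniform point cloud, sized so the
    threshold graph is neither empty nor complete."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, 2.0, size=(n, 3))
    return rips_filtration(pts, max_dim, radius)


@pytest.fixture
def random_rips_complexes():
    """Sublevel complexes of 25 random Rips filtrations at their top value."""
    return [random_rips(seed).complex for seed in range(25)]
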