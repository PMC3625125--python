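import numpy as np
import pytest

from spmtopo.topology import build_complex, mesh_complex


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def octahedron_triangles():
    """Closed genus-0 triangulation: 6 vertices, 12 edges, 8 faces."""
    return np.array([
        [0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
        [0, 2, 5], [2, 1, 5], [1, 3, 5], [3, 0, 5],
    ])


@pytest.fixture(scope="session")
def two_boxes_complex():
    """Two disjoint solid 3D boxes in one mask."""
    mask = np.zeros((4, 9, 4), dtype=bool)
    mask[:, :4] = True
    mask[:, 6:] = True
    return build_complex(mask)


@pytest.fixture(scope="session")
def two_octahedra_complex(octahedron_triangles=None):
    tri = np.array([
        [0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
        [0, 2, 5], [2, 1, 5], [1, 3, 5], [3, 0, 5],
    ])
    return mesh_complex(np.vstack([tri, tri + 6]))
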