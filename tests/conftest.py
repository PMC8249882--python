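import numpy as np
import pytest

from cortexshift.meshcore import SurfaceMesh, build_parcellation, medial_wall_mask
from cortexshift.synth import make_icosphere, make_pseudocortex


@pytest.fixture(scope="session")
def ico3():
    """Level-3 icosphere of cortical size (642 vertices)."""
    return make_icosphere(3, 80.0)


@pytest.fixture(scope="session")
def pseudo3():
    """A folded pseudocortex with its spherical parameterization."""
    return make_pseudocortex(3, 80.0, 0.15, seed=7)


@pytest.fixture(scope="session")
def cortex_mask3(ico3):
    parc = build_parcellation(ico3)
    wall, cortex = medial_wall_mask(parc, wall_roi=0)
    return wall, cortex


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planar_grid():
    """A triangulated regular planar grid (for smoothing/geodesic oracles)."""
    n = 15
    spacing = 2.0
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return SurfaceMesh(verts, np.array(faces), "grid"), n, spacing
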