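import numpy as np
import pytest

from ssimfem.meshes import TetMesh
from ssimfem.synthetic import GeneratorConfig, make_template, sample_cohort


@pytest.fixture(scope="session")
def template():
    return make_template(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap default-structure cohort for smoke-level checks."""
    return sample_cohort(GeneratorConfig(seed=0, n_subjects=40,
                                         n_elements=200))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """Tetrahedralised unit cube (Delaunay of the 8 corners)."""
    from scipy.spatial import Delaunay

    corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                        for k in (0, 1)], dtype=float)
    tri = Delaunay(corners)
    return TetMesh(corners, tri.simplices).orient_positive()


@pytest.fixture(scope="session")
def two_tet_mesh():
    """Two tets sharing face BCD; volumes 1/6 and 1/3, frontal shadow
    area exactly 1 (hand geometry used by the aBMD-analog test)."""
    pts = np.array([
        [0.0, 0.0, 0.0],   # A
        [1.0, 0.0, 0.0],   # B
        [0.0, 0.0, 1.0],   # C
        [0.0, 1.0, 0.0],   # D
        [1.0, 1.0, 1.0],   # E
    ])
    cells = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    return TetMesh(pts, cells).orient_positive()
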