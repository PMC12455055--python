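import numpy as np
import pytest

from ceidr.surface import SurfaceMesh, build_neighborhood_index, make_icosphere


def make_path_mesh(n: int, spacing: float = 4.0) -> SurfaceMesh:
    """Collinear chain of n vertices along the x-axis.

    Faces chain consecutive triples, so edges connect i to i+1 and i to i+2;
    all edge weights equal their Euclidean (straight-line) lengths.
    """
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    faces = np.array([[i, i + 1, i + 2] for i in range(n - 2)], dtype=np.int64)
    return SurfaceMesh(coordinates=coords, faces=faces)


def make_triangle_mesh(edge: float = 1.0) -> SurfaceMesh:
    """Single equilateral triangle: every vertex neighbors every other."""
    coords = edge * np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0]]
    )
    return SurfaceMesh(coordinates=coords, faces=np.array([[0, 1, 2]]))


@pytest.fixture(scope="session")
def ico2_mesh() -> SurfaceMesh:
    """162-vertex icosphere at study-like vertex density (edge ~2 mm)."""
    return make_icosphere(2, 14.0)


@pytest.fixture(scope="session")
def study_mesh() -> SurfaceMesh:
    """The 642-vertex desk-scale stand-in for a hemisphere."""
    return make_icosphere(3, 28.0)


@pytest.fixture(scope="session")
def study_index(study_mesh):
    return build_neighborhood_index(
        study_mesh, radius_grid=sorted({float(r) for r in range(16)} | {16.0})
    )
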