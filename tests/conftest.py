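import numpy as np
import pytest

from dinomorph.mesh_core import TriMesh, contains_points
from dinomorph.synthetic_data import (generate_skeleton, prismatic_test_body,
                                      synthetic_tyrannosaur, tyrannosaur_params)


def unit_cube_mesh(origin=(0.0, 0.0, 0.0), side=1.0) -> TriMesh:
    """Closed unit cube with outward winding (volume = side^3)."""
    o = np.asarray(origin, dtype=float)
    v = o + side * np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
                  [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
                  [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]])
    return TriMesh(v, f)


def voxel_mass_properties(mesh: TriMesh, n: int = 36):
    """Independent voxel-counting oracle for volume and COM.

    Returns (volume, com, voxel size); accuracy is limited by the surface
    band of half-filled voxels, roughly ``0.5 * surface_area * h``.
    """
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    h = (hi - lo).max() / n
    axes = [np.arange(lo[i] + h / 2, hi[i], h) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
    inside = contains_points(mesh, grid)
    return inside.sum() * h ** 3, grid[inside].mean(axis=0), h


@pytest.fixture
def unit_cube():
    return unit_cube_mesh()


@pytest.fixture(scope="session")
def tyrannosaur_body():
    return synthetic_tyrannosaur()


@pytest.fixture(scope="session")
def tyrannosaur_skeleton():
    return generate_skeleton(tyrannosaur_params())


@pytest.fixture(scope="session")
def prismatic_body():
    return prismatic_test_body()
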