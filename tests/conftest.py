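import numpy as np
import pytest
import trimesh

import organmorph as om


@pytest.fixture(scope="session")
def sphere20():
    """Digitised sphere R=20 mm at 1 mm isotropic spacing, with truth."""
    return om.make_sphere(20.0)


@pytest.fixture(scope="session")
def sphere20_mesh(sphere20):
    vol, _ = sphere20
    return om.reconstruct_organ(vol)


@pytest.fixture(scope="session")
def icosphere25():
    """Fine analytic sphere mesh R=25 mm (exact vertices on the sphere)."""
    tm = trimesh.creation.icosphere(subdivisions=4, radius=25.0)
    return om.TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@pytest.fixture(scope="session")
def flat_patch():
    """Regular planar triangulated grid patch in the z=0 plane."""
    n = 9
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return om.TriMesh(verts, np.asarray(faces)), n


@pytest.fixture
def tetrahedron():
    """Regular tetrahedron centred at the origin, outward wound."""
    verts = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    mesh = om.TriMesh(verts, faces)
    if mesh.signed_volume() < 0:
        mesh = om.TriMesh(verts, faces[:, ::-1])
    return mesh
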