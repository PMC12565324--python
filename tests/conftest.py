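import numpy as np
import pytest

from morphocavity.synthetic import CavityParams, generate_specimen, generate_template


@pytest.fixture(scope="session")
def template():
    """Default template at a resolution where landmarks sit on grid vertices."""
    return generate_template(resolution=20)


@pytest.fixture(scope="session")
def template_fine():
    return generate_template(resolution=40)


@pytest.fixture(scope="session")
def deformed_specimen():
    """A widened/shallowed specimen with exact (noise-free) landmarks."""
    params = CavityParams(
        anterior_width=10.5,
        posterior_superior_width=8.8,
        inferior_width=5.0,
        depth=31.0,
        frontal_curvature=2.5,
    )
    mesh, config = generate_specimen(params, seed=1, resolution=20)
    return mesh, config


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_plane_mesh(half: float = 10.0):
    """Two triangles tiling the square [-half, half]^2 at z = 0."""
    from morphocavity.geometry_io import TriangleMesh

    v = np.array(
        [[-half, -half, 0], [half, -half, 0], [half, half, 0], [-half, half, 0]],
        float,
    )
    t = np.array([[0, 1, 2], [0, 2, 3]])
    return TriangleMesh(v, t)


def make_sphere_mesh(radius: float = 1.0, n_theta: int = 24, n_phi: int = 48):
    """UV sphere triangulation (poles collapsed)."""
    from morphocavity.geometry_io import TriangleMesh

    theta = np.linspace(0, np.pi, n_theta + 1)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    verts = []
    for t in theta:
        for p in phi:
            verts.append(
                [
                    radius * np.sin(t) * np.cos(p),
                    radius * np.sin(t) * np.sin(p),
                    radius * np.cos(t),
                ]
            )
    verts = np.array(verts)
    tris = []
    for i in range(n_theta):
        for j in range(n_phi):
            a = i * n_phi + j
            b = i * n_phi + (j + 1) % n_phi
            c = (i + 1) * n_phi + j
            d = (i + 1) * n_phi + (j + 1) % n_phi
            tris.append([a, b, d])
            tris.append([a, d, c])
    mesh = TriangleMesh(verts, np.array(tris))
    # drop degenerate pole triangles
    areas = mesh.triangle_areas()
    return TriangleMesh(mesh.vertices, mesh.triangles[areas > 1e-12])
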