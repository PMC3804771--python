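import numpy as np
import pytest

from cortiparc.icosphere import build_icosphere
from cortiparc.mesh import TriangleMesh


def icosphere_mesh(level: int, radius: float = 1.0) -> TriangleMesh:
    ico = build_icosphere(level)
    return TriangleMesh(radius * ico.vertices, ico.triangles.copy())


def torus_mesh(m: int = 16, n: int = 8, R: float = 2.0, r: float = 0.7) -> TriangleMesh:
    """Closed triangulated torus on an m x n parameter grid."""
    u = 2 * np.pi * np.arange(m) / m
    v = 2 * np.pi * np.arange(n) / n
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (R + r * np.cos(vv)) * np.cos(uu)
    y = (R + r * np.cos(vv)) * np.sin(uu)
    z = r * np.sin(vv)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    tris = []
    for i in range(m):
        for j in range(n):
            a = i * n + j
            b = ((i + 1) % m) * n + j
            c = i * n + (j + 1) % n
            d = ((i + 1) % m) * n + (j + 1) % n
            tris.append((a, b, d))
            tris.append((a, d, c))
    return TriangleMesh(verts, np.array(tris))


def bump_field(points: np.ndarray, seed: int = 11, n: int = 40, width: float = 0.25):
    """Sulcus-like scalar field on unit points: signed Gaussian bumps."""
    rng = np.random.default_rng(seed)
    c = rng.normal(size=(n, 3))
    c /= np.linalg.norm(c, axis=1, keepdims=True)
    s = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    ang = np.arccos(np.clip(points @ c.T, -1.0, 1.0))
    return np.exp(-(ang**2) / (2 * width**2)) @ s


@pytest.fixture(scope="session")
def small_template():
    """Coarse synthetic template (level-4 mesh) for mapping/feature tests."""
    from cortiparc.synthetic import SyntheticCohortSpec, make_template

    return make_template(SyntheticCohortSpec(seed=2, mesh_level=4))
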