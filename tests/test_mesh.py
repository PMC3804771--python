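import numpy as np
import pytest

from cortiparc.mesh import (
    TriangleMesh,
    TopologyError,
    genus,
    laplacian_smooth,
    triangle_areas,
    vertex_areas,
)

from conftest import icosphere_mesh, torus_mesh


def glue_tori():
    """Genus-2 surface: two tori glued along one removed triangle each."""
    t1 = torus_mesh(12, 6)
    t2 = torus_mesh(12, 6)
    f1 = t1.triangles[0]
    f2 = t2.triangles[0]
    tris1 = np.delete(t1.triangles, 0, axis=0)
    tris2 = np.delete(t2.triangles, 0, axis=0)
    # identify f2's corners with f1's (reversed order so orientations mate)
    offset = t1.n_vertices
    remap = np.arange(t2.n_vertices) + offset
    for a, b in zip(f2, f1[::-1]):
        remap[a] = b
    tris2 = remap[tris2]
    verts = np.vstack([t1.vertices, t2.vertices + [10.0, 0, 0]])
    tris = np.vstack([tris1, tris2])
    # compact away the three orphaned (merged-out) vertices
    used = np.unique(tris)
    index = np.full(len(verts), -1, dtype=np.int64)
    index[used] = np.arange(len(used))
    return TriangleMesh(verts[used], index[tris])


class TestGenus:
    def test_sphere_torus_double_torus(self):
        assert genus(icosphere_mesh(0)) == 0
        assert genus(torus_mesh()) == 1
        assert genus(glue_tori()) == 2

    def test_open_mesh_rejected(self):
        m = icosphere_mesh(0)
        open_mesh = TriangleMesh(m.vertices, m.triangles[:-1])
        with pytest.raises(TopologyError):
            genus(open_mesh)

    def test_inconsistent_orientation_rejected(self):
        m = icosphere_mesh(0)
        tris = m.triangles.copy()
        tris[0] = tris[0][::-1]
        with pytest.raises(TopologyError):
            genus(TriangleMesh(m.vertices, tris))


class TestLaplacianSmooth:
    def test_zero_iterations_is_identity(self):
        m = icosphere_mesh(1)
        out = laplacian_smooth(m, iterations=0)
        np.testing.assert_array_equal(out.vertices, m.vertices)

    def test_apex_moves_toward_ring_centroid(self):
        # hexagonal fan: apex at (0,0,1), ring centered on the origin
        ang = 2 * np.pi * np.arange(6) / 6
        verts = np.vstack([[0, 0, 1.0], np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])])
        tris = np.array([(0, 1 + i, 1 + (i + 1) % 6) for i in range(6)])
        out = laplacian_smooth(TriangleMesh(verts, tris), iterations=1, relaxation=0.1)
        np.testing.assert_allclose(out.vertices[0], [0, 0, 0.9], atol=1e-12)

    def test_vertex_at_centroid_fixed(self):
        ang = 2 * np.pi * np.arange(6) / 6
        verts = np.vstack([[0, 0, 0.0], np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])])
        tris = np.array([(0, 1 + i, 1 + (i + 1) % 6) for i in range(6)])
        out = laplacian_smooth(TriangleMesh(verts, tris), iterations=1, relaxation=0.5)
        np.testing.assert_allclose(out.vertices[0], [0, 0, 0], atol=1e-12)

    def test_connectivity_and_fields_unchanged(self):
        m = icosphere_mesh(1)
        m.scalar_fields["f"] = np.arange(m.n_vertices, dtype=float)
        out = laplacian_smooth(m, 3, 0.2)
        np.testing.assert_array_equal(out.triangles, m.triangles)
        np.testing.assert_array_equal(out.scalar_fields["f"], m.scalar_fields["f"])


class TestVertexAreas:
    def test_tetrahedron_symmetry(self):
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        tris = np.array([(0, 1, 2), (0, 3, 1), (0, 2, 3), (1, 3, 2)])
        m = TriangleMesh(verts, tris)
        va = vertex_areas(m)
        np.testing.assert_allclose(va, va[0])
        np.testing.assert_allclose(va.sum(), triangle_areas(m).sum(), rtol=1e-12)

    def test_conservation(self):
        m = icosphere_mesh(2)
        np.testing.assert_allclose(
            vertex_areas(m).sum(), triangle_areas(m).sum(), rtol=1e-9
        )

    def test_icosphere_total_area_near_sphere(self):
        m = icosphere_mesh(3)
        assert vertex_areas(m).sum() == pytest.approx(4 * np.pi, rel=0.01)


class TestDecimate:
    def test_noop_at_current_count(self):
        from cortiparc.decimate import decimate

        m = icosphere_mesh(2)
        out = decimate(m, m.n_triangles)
        np.testing.assert_array_equal(out.triangles, m.triangles)

    def test_exact_target_and_genus_on_sphere(self):
        from cortiparc.decimate import decimate

        m = icosphere_mesh(3)
        out = decimate(m, 640)
        assert out.n_triangles == 640
        assert genus(out) == 0

    def test_torus_keeps_genus(self):
        from cortiparc.decimate import decimate

        m = torus_mesh(24, 12)
        out = decimate(m, m.n_triangles // 2)
        assert genus(out) == 1

    def test_fields_carried(self):
        from cortiparc.decimate import decimate

        m = icosphere_mesh(2)
        m.scalar_fields["f"] = m.vertices[:, 2].copy()
        m.labels = (m.vertices[:, 2] > 0).astype(np.int64)
        out = decimate(m, 160)
        assert set(out.scalar_fields) == {"f"}
        assert len(out.scalar_fields["f"]) == out.n_vertices
        assert out.labels is not None and len(out.labels) == out.n_vertices

    def test_target_below_four_rejected(self):
        from cortiparc.decimate import decimate

        with pytest.raises(ValueError):
            decimate(icosphere_mesh(1), 2)
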