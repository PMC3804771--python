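import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cortiparc.registration import (
    DeformationField,
    DemonsParams,
    RotationParams,
    compose,
    demons_register,
    exp_map,
    field_of_rotation,
    grid_ops,
    log_map,
    rotation_register,
    smooth_deformation,
    tangent_project,
)
from cortiparc.sphere import spherical_orientations
from cortiparc.synthetic import random_tangent_warp

from conftest import bump_field


class TestExpMap:
    def test_zero_tangent_identity(self):
        p = np.array([0.0, 0.0, 1.0])
        np.testing.assert_array_equal(exp_map(p, np.zeros(3)), p)

    def test_quarter_great_circle_exact(self):
        p = np.array([0.0, 0.0, 1.0])
        t = (np.pi / 2) * np.array([1.0, 0.0, 0.0])
        np.testing.assert_allclose(exp_map(p, t), [1, 0, 0], atol=1e-12)

    def test_norm_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(100, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        t = tangent_project(p, rng.normal(scale=0.5, size=(100, 3)))
        out = exp_map(p, t)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)

    def test_non_orthogonal_rejected(self):
        with pytest.raises(ValueError):
            exp_map(np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, 0.1]))

    def test_log_inverts_exp(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(50, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        t = tangent_project(p, rng.normal(scale=0.3, size=(50, 3)))
        np.testing.assert_allclose(log_map(p, exp_map(p, t)), t, atol=1e-9)


class TestSmoothDeformation:
    def test_zero_field_fixed(self):
        ops = grid_ops(2)
        out = smooth_deformation(DeformationField.zero(ops.grid), ops=ops)
        assert np.all(out.vectors == 0)

    def test_impulse_magnitude_decreases(self):
        ops = grid_ops(2)
        vec = np.zeros((ops.grid.n_vertices, 3))
        vec[5] = tangent_project(ops.grid.vertices[[5]], np.array([[0.1, 0.2, 0.0]]))[0]
        out = smooth_deformation(DeformationField(ops.grid, vec), iterations=1, ops=ops)
        assert np.linalg.norm(out.vectors[5]) < np.linalg.norm(vec[5])

    def test_rotational_field_nearly_preserved(self):
        # the tangent field of a fixed infinitesimal rotation (a Killing
        # field) is preserved by transport-averaging up to a discretization
        # error that shrinks under grid refinement
        omega = np.array([0.0, 0.0, 0.02])
        devs = {}
        for lvl in (3, 4, 5):
            ops = grid_ops(lvl)
            V = ops.grid.vertices
            vec = np.cross(np.broadcast_to(omega, V.shape), V)
            out = smooth_deformation(
                DeformationField(ops.grid, vec), iterations=40, ops=ops
            )
            devs[lvl] = np.abs(out.vectors - vec).max() / np.linalg.norm(omega)
        assert devs[4] < 0.02  # ~2% after a full 40-iteration pass
        assert devs[5] < devs[4] < devs[3]

    def test_roughness_reduced(self):
        ops = grid_ops(3)
        rng = np.random.default_rng(0)
        vec = tangent_project(ops.grid.vertices, rng.normal(scale=0.02, size=(ops.grid.n_vertices, 3)))
        fld = DeformationField(ops.grid, vec)

        def roughness(f):
            d = f.vectors[ops.safe_nbr] - f.vectors[:, None, :]
            d[~ops.nbr_mask] = 0
            return float((d**2).sum())

        out = smooth_deformation(fld, iterations=10, ops=ops)
        assert roughness(out) < roughness(fld)


class TestCompose:
    def test_identity_rotation(self):
        ops = grid_ops(2)
        rng = np.random.default_rng(2)
        vec = tangent_project(ops.grid.vertices, rng.normal(scale=0.02, size=(ops.grid.n_vertices, 3)))
        F = DeformationField(ops.grid, vec)
        out = compose(Rotation.identity(), F)
        np.testing.assert_allclose(out.vectors, F.vectors, atol=1e-12)

    def test_rotation_with_zero_field(self):
        ops = grid_ops(2)
        R = Rotation.from_rotvec([0.0, 0.03, 0.01])
        out = compose(R, DeformationField.zero(ops.grid))
        np.testing.assert_allclose(
            out.vectors, field_of_rotation(R, ops.grid).vectors, atol=1e-12
        )

    def test_pointwise_oracle(self):
        ops = grid_ops(2)
        rng = np.random.default_rng(3)
        vec = tangent_project(ops.grid.vertices, rng.normal(scale=0.02, size=(ops.grid.n_vertices, 3)))
        F = DeformationField(ops.grid, vec)
        R = Rotation.from_rotvec([0.02, -0.01, 0.04])
        out = compose(R, F)
        expected = R.apply(exp_map(ops.grid.vertices, vec, check=False))
        np.testing.assert_allclose(out.warp_positions(), expected, atol=1e-9)


class TestRotationRegister:
    def test_identity_when_aligned(self):
        ops = grid_ops(4)
        f = bump_field(ops.grid.vertices)
        R = rotation_register(f, f, RotationParams(), ops=ops)
        assert np.linalg.norm(R.as_rotvec()) < 1e-3

    @pytest.mark.parametrize("deg", [0.5, 2.0, 5.0])
    def test_known_rotation_recovered(self, deg):
        ops = grid_ops(4)
        axis = np.array([0.3, 0.5, np.sqrt(1 - 0.34)])
        R0 = Rotation.from_rotvec(np.radians(deg) * axis)
        f = bump_field(ops.grid.vertices)
        m = bump_field(R0.inv().apply(ops.grid.vertices))
        R = rotation_register(f, m, RotationParams(), level_index=1, ops=ops)
        err = np.degrees(np.linalg.norm((R * R0.inv()).as_rotvec()))
        assert err < 0.5

    def test_never_worse_than_identity(self):
        ops = grid_ops(3)
        rng = np.random.default_rng(4)
        f = bump_field(ops.grid.vertices)
        m = bump_field(ops.grid.vertices, seed=99)  # unrelated field
        R = rotation_register(f, m, RotationParams(), ops=ops)
        from cortiparc.registration import _rotation_metric

        assert _rotation_metric(f, m, ops, R) <= _rotation_metric(
            f, m, ops, Rotation.identity()
        ) + 1e-15


class TestDemons:
    def test_zero_force_when_aligned(self):
        ops = grid_ops(3)
        f = bump_field(ops.grid.vertices)
        out = demons_register(f, f, DemonsParams(), ops=ops)
        assert out.magnitudes().max() < 1e-6

    def test_known_warp_reduces_endpoint_error(self):
        ops = grid_ops(4)
        V = ops.grid.vertices
        rng = np.random.default_rng(0)
        w = random_tangent_warp(V, ops.grid.triangles, rng, 0.5 * ops.h_min, 0.6)
        Wtrue = exp_map(V, w, check=False)
        fixed = bump_field(Wtrue)
        moving = bump_field(V)
        out = demons_register(fixed, moving, DemonsParams(), ops=ops)
        W = out.warp_positions()
        err = np.arccos(np.clip(np.einsum("ij,ij->i", W, Wtrue), -1, 1)).mean()
        base = np.arccos(np.clip(np.einsum("ij,ij->i", V, Wtrue), -1, 1)).mean()
        assert err < 0.5 * base
        # invariants: tangency, unit norm, no inverted triangles
        assert np.abs(np.einsum("ij,ij->i", V, out.vectors)).max() < 1e-9
        np.testing.assert_allclose(np.linalg.norm(W, axis=1), 1.0, atol=1e-9)
        assert (spherical_orientations(W, ops.grid.triangles) > 0).all()

    def test_metric_not_increased(self):
        ops = grid_ops(3)
        V = ops.grid.vertices
        rng = np.random.default_rng(5)
        w = random_tangent_warp(V, ops.grid.triangles, rng, 0.4 * ops.h_min, 0.6)
        fixed = bump_field(exp_map(V, w, check=False))
        moving = bump_field(V)
        out = demons_register(fixed, moving, DemonsParams(), ops=ops)
        m0 = np.mean((ops.locator.interpolate(moving, V) - fixed) ** 2)
        m1 = np.mean((ops.locator.interpolate(moving, out.warp_positions()) - fixed) ** 2)
        assert m1 <= m0


class TestEquivariance:
    def test_metric_invariant_under_global_rotation(self):
        # rotating both input fields by the same rotation leaves the
        # mean-squared metric unchanged (up to resampling error)
        ops = grid_ops(3)
        V = ops.grid.vertices
        f = bump_field(V)
        m = bump_field(V, seed=13)
        R = Rotation.from_rotvec([0.0, 0.0, 2 * np.pi / 5])  # icosahedral symmetry
        fR = ops.locator.interpolate(f, R.inv().apply(V))
        mR = ops.locator.interpolate(m, R.inv().apply(V))
        metric = np.mean((f - m) ** 2)
        metricR = np.mean((fR - mR) ** 2)
        assert metricR == pytest.approx(metric, abs=1e-6)
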