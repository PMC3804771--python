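"""Spherical registration engine: exponential-map geometry, rotational
(versor) pre-alignment, spherical diffeomorphic demons, deformation-field
smoothing/composition, and the multi-resolution driver.

A deformation is stored as one tangent vector per vertex of a fixed
icosahedral grid; applying it moves each grid vertex along the great
circle in the vector's direction by the vector's length (the spherical
exponential map), which keeps every warp a bijection of the sphere as
long as updates stay well inside the injectivity radius.  Demons velocity
updates are computed in a per-vertex tangent chart, capped at half the
grid's shortest edge length (the self-regulated mode), exponentiated,
composed with the running warp, and regularized by iterated
parallel-transport averaging of the tangent field.

Registration runs coarse to fine over the grid/feature schedule
(IC4/IS-distance, IC5/AP-distance, IC6/hull-depth, IC7/mean-curvature by
default), with a global rotation re-estimated at each level before the
demons stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

from . import features as feat
from .icosphere import (
    IcoMesh,
    SphericalLocator,
    build_icosphere,
    shortest_edge_length,
)
from .sphere import SphereMesh, spherical_orientations

log = logging.getLogger(__name__)

__all__ = [
    "exp_map",
    "log_map",
    "parallel_transport",
    "DeformationField",
    "RotationParams",
    "DemonsParams",
    "ScheduleLevel",
    "default_schedule",
    "rotation_register",
    "demons_register",
    "smooth_deformation",
    "compose",
    "multires_register",
    "GridOps",
]


# ------------------------------------------------------------ sphere calculus


def exp_map(point: np.ndarray, tangent: np.ndarray, check: bool = True) -> np.ndarray:
    """Geodesic step on the unit sphere: cos(|t|) p + sin(|t|) t/|t|.

    ``point`` and ``tangent`` may be single vectors or (N, 3) arrays;
    tangents must be orthogonal to their base points (checked to 1e-6).
    """
    p = np.atleast_2d(np.asarray(point, dtype=float))
    t = np.atleast_2d(np.asarray(tangent, dtype=float))
    if check:
        dots = np.abs(np.einsum("ij,ij->i", p, t))
        if np.any(dots > 1e-6):
            raise ValueError("tangent vector not orthogonal to base point")
    nrm = np.linalg.norm(t, axis=1)
    safe = np.where(nrm > 0, nrm, 1.0)
    out = np.cos(nrm)[:, None] * p + np.sin(nrm)[:, None] * (t / safe[:, None])
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out[0] if np.asarray(point).ndim == 1 else out


def log_map(point: np.ndarray, target: np.ndarray, max_angle: float = 0.5 * np.pi):
    """Tangent vector at ``point`` whose exponential reaches ``target``.

    Raises if any pair is separated by more than ``max_angle`` (the log is
    not robust near the antipode, and warps beyond a quarter turn indicate
    a registration failure anyway).
    """
    p = np.atleast_2d(np.asarray(point, dtype=float))
    q = np.atleast_2d(np.asarray(target, dtype=float))
    c = np.clip(np.einsum("ij,ij->i", p, q), -1.0, 1.0)
    ang = np.arccos(c)
    if np.any(ang > max_angle):
        raise ValueError(
            f"log map requested across {np.degrees(ang.max()):.1f} deg > "
            f"{np.degrees(max_angle):.1f} deg"
        )
    d = q - c[:, None] * p
    nrm = np.linalg.norm(d, axis=1)
    safe = np.where(nrm > 1e-300, nrm, 1.0)
    out = (ang / safe)[:, None] * d
    out[nrm <= 1e-300] = 0.0
    return out[0] if np.asarray(point).ndim == 1 else out


def parallel_transport_matrix(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation matrices transporting tangent vectors at ``src`` points to
    the tangent planes at ``dst`` points along the connecting geodesics."""
    a = np.cross(src, dst)
    s = np.linalg.norm(a, axis=1)
    c = np.einsum("ij,ij->i", src, dst)
    eye = np.eye(3)
    out = np.empty((len(src), 3, 3))
    small = s < 1e-14
    axis = a / np.where(small, 1.0, s)[:, None]
    K = np.zeros((len(src), 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    out[:] = eye + s[:, None, None] * K + (1 - c)[:, None, None] * (K @ K)
    out[small] = eye
    return out


def parallel_transport(vec: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    R = parallel_transport_matrix(np.atleast_2d(src), np.atleast_2d(dst))
    v = np.atleast_2d(vec)
    out = np.einsum("nij,nj->ni", R, v)
    return out[0] if np.asarray(vec).ndim == 1 else out


def tangent_project(points: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Remove the radial component so vectors lie in the tangent planes."""
    d = np.einsum("ij,ij->i", points, vectors)
    return vectors - d[:, None] * points


# ------------------------------------------------------------------ datatypes


@dataclass
class DeformationField:
    """Tangent vectors at the vertices of a fixed icosahedral grid."""

    base: IcoMesh
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (self.base.n_vertices, 3):
            raise ValueError("one tangent vector per base vertex required")

    @classmethod
    def zero(cls, base: IcoMesh) -> "DeformationField":
        return cls(base, np.zeros((base.n_vertices, 3)))

    def warp_positions(self) -> np.ndarray:
        """Unit positions each base vertex is carried to."""
        return exp_map(self.base.vertices, self.vectors, check=False)

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


@dataclass
class RotationParams:
    """Regular-step gradient-descent settings of the versor stage.

    ``max_step_length`` applies at the first schedule level and is divided
    by 2^(i-1) at level i.
    """

    gradient_magnitude_tolerance: float = 1e-6
    max_step_length: float = 0.01
    min_step_length: float = 1e-9
    relaxation_factor: float = 0.9
    max_iterations: int = 30

    def __post_init__(self):
        if not 0 < self.relaxation_factor < 1:
            raise ValueError("relaxation_factor must be in (0, 1)")
        if not self.min_step_length < self.max_step_length:
            raise ValueError("min_step_length must be < max_step_length")


@dataclass
class DemonsParams:
    """Spherical demons settings.

    sigma scales with the grid's shortest edge length h (sigma =
    sigma_scale * h); epsilon = 1/sigma^2 bounds the largest update step
    at sigma/2, and the self-regulated mode additionally hard-caps steps
    at half the shortest edge so single-step exponentiation stays inside
    the injectivity radius.  ``min_metric_change`` is the relative
    mean-squared-metric improvement below which iteration stops.
    """

    sigma_scale: float = 1.0
    lambda_def: float = 1.0
    self_regulated: bool = True
    min_metric_change: float = 0.05
    max_iterations: int = 500
    smoothing_iterations: int = 40

    def epsilon(self, h: float) -> float:
        sigma = self.sigma_scale * h
        return 1.0 / sigma**2


@dataclass(frozen=True)
class ScheduleLevel:
    """One row of the multi-resolution schedule."""

    index: int  # 1-based refinement level i
    ico_level: int
    feature: str
    normalization: str  # piecewise_rescale | histogram_match | clamp
    lambda_feat: float


def default_schedule(max_levels: int = 4) -> list[ScheduleLevel]:
    """The shipped four-level schedule (truncate with ``max_levels``)."""
    rows = [
        ScheduleLevel(1, 4, "is_distance", "piecewise_rescale", 0.5),
        ScheduleLevel(2, 5, "ap_distance", "piecewise_rescale", 0.5),
        ScheduleLevel(3, 6, "hull_depth", "histogram_match", 0.5),
        ScheduleLevel(4, 7, "mean_curvature", "clamp", 1.0),
    ]
    return rows[:max_levels]


# --------------------------------------------------------------- grid caches


class GridOps:
    """Cached per-grid structures: locator, padded 1-ring table, tangent
    bases, least-squares gradient operators, and per-edge parallel
    transports."""

    def __init__(self, grid: IcoMesh):
        self.grid = grid
        self.locator = SphericalLocator(grid.vertices, grid.triangles)
        self.h_min = shortest_edge_length(grid)
        V, T = grid.vertices, grid.triangles
        n = len(V)
        nbr_sets = [set() for _ in range(n)]
        for a, b, c in T:
            nbr_sets[a].update((b, c))
            nbr_sets[b].update((a, c))
            nbr_sets[c].update((a, b))
        width = max(len(s) for s in nbr_sets)
        self.nbr = np.full((n, width), -1, dtype=np.int64)
        for v, s in enumerate(nbr_sets):
            idx = sorted(s)
            self.nbr[v, : len(idx)] = idx
        self.nbr_mask = self.nbr >= 0
        self.nbr_count = self.nbr_mask.sum(axis=1)
        safe_nbr = np.where(self.nbr < 0, 0, self.nbr)
        self.safe_nbr = safe_nbr
        # deterministic tangent basis
        nrm = V
        a = np.zeros_like(V)
        smallest = np.argmin(np.abs(V), axis=1)
        a[np.arange(n), smallest] = 1.0
        e1 = np.cross(nrm, a)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(nrm, e1)
        self.basis = np.stack([e1, e2], axis=1)  # (n, 2, 3)
        # gradient operator: 2D neighbor offsets + normal-equation inverses
        diff = V[safe_nbr] - V[:, None, :]  # (n, k, 3)
        diff = diff - np.einsum("nkj,nj->nk", diff, V)[:, :, None] * V[:, None, :]
        b = np.einsum("nkj,ndj->nkd", diff, self.basis)  # (n, k, 2)
        b[~self.nbr_mask] = 0.0
        M = np.einsum("nkd,nke->nde", b, b)
        self.grad_b = b
        self.grad_Minv = np.linalg.inv(M)
        # parallel transport from each neighbor into each vertex's plane
        src = V[safe_nbr].reshape(-1, 3)
        dst = np.repeat(V, width, axis=0)
        self.transport = parallel_transport_matrix(src, dst).reshape(n, width, 3, 3)

    def surface_gradient(self, values: np.ndarray) -> np.ndarray:
        """Per-vertex tangent-plane gradient of a grid scalar field by
        weighted least squares over the 1-ring."""
        s = np.asarray(values, dtype=float)
        ds = s[self.safe_nbr] - s[:, None]
        ds[~self.nbr_mask] = 0.0
        rhs = np.einsum("nkd,nk->nd", self.grad_b, ds)
        g2 = np.einsum("nde,ne->nd", self.grad_Minv, rhs)
        return np.einsum("nd,ndj->nj", g2, self.basis)


@lru_cache(maxsize=8)
def grid_ops(level: int) -> GridOps:
    return GridOps(build_icosphere(level))


# ------------------------------------------------------------------ smoothing


def smooth_deformation(
    field: DeformationField,
    iterations: int = 40,
    lambda_def: float = 1.0,
    ops: GridOps | None = None,
) -> DeformationField:
    """Regularize a tangent field by iterated 1-ring averaging.

    Each neighbor's vector is parallel-transported into the center
    vertex's tangent plane before averaging; the blended result is
    re-projected to the tangent plane.  The per-iteration blend weight is
    lambda / (4 (1 + lambda)), i.e. a per-iteration diffusion length of
    about half an edge, so the default 40 iterations approximate a
    compact Gaussian regularizer of roughly two edge lengths.  Fields
    generated by a global infinitesimal rotation are fixed points of this
    operator.
    """
    if ops is None:
        ops = grid_ops(field.base.level)
    V = field.base.vertices
    vec = field.vectors.copy()
    if iterations == 0 or lambda_def == 0:
        return DeformationField(field.base, vec)
    beta = lambda_def / (4.0 * (1.0 + lambda_def))
    cnt = np.where(ops.nbr_count == 0, 1, ops.nbr_count)
    for _ in range(iterations):
        moved = np.einsum("nkij,nkj->nki", ops.transport, vec[ops.safe_nbr])
        moved[~ops.nbr_mask] = 0.0
        ringmean = moved.sum(axis=1) / cnt[:, None]
        vec = (1.0 - beta) * vec + beta * ringmean
        vec = tangent_project(V, vec)
    return DeformationField(field.base, vec)


# ------------------------------------------------------------------- rotation


def _rotation_metric(fixed, moving, ops: GridOps, R: Rotation) -> float:
    pos = R.apply(ops.grid.vertices)
    warped = ops.locator.interpolate(moving, pos)
    return float(np.mean((warped - fixed) ** 2))


def rotation_register(
    fixed: np.ndarray,
    moving: np.ndarray,
    params: RotationParams | None = None,
    level_index: int = 1,
    ops: GridOps | None = None,
    grid: IcoMesh | None = None,
) -> Rotation:
    """Global rotational (versor) alignment of two grid scalar fields.

    Minimizes the mean-squared feature difference over the rotation group
    by regular-step gradient descent: the step length starts at
    max_step / 2^(i-1), relaxes by the relaxation factor whenever the
    gradient reverses direction, and iteration stops on the gradient
    tolerance, the minimum step, or the iteration cap.  The returned
    rotation never scores worse than the identity.
    """
    params = params or RotationParams()
    if ops is None:
        if grid is None:
            raise ValueError("need ops or grid")
        ops = GridOps(grid)
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    R = Rotation.identity()
    step = params.max_step_length / (2.0 ** (level_index - 1))
    best = (_rotation_metric(fixed, moving, ops, R), R)
    prev_g = None
    delta = 1e-4
    for _ in range(params.max_iterations):
        g = np.zeros(3)
        for k in range(3):
            dv = np.zeros(3)
            dv[k] = delta
            mp = _rotation_metric(fixed, moving, ops, Rotation.from_rotvec(dv) * R)
            mm = _rotation_metric(fixed, moving, ops, Rotation.from_rotvec(-dv) * R)
            g[k] = (mp - mm) / (2 * delta)
        gn = np.linalg.norm(g)
        if gn < params.gradient_magnitude_tolerance:
            break
        if prev_g is not None and np.dot(g, prev_g) < 0:
            step *= params.relaxation_factor
        if step < params.min_step_length:
            break
        prev_g = g
        R = Rotation.from_rotvec(-step * g / gn) * R
        m = _rotation_metric(fixed, moving, ops, R)
        if m < best[0]:
            best = (m, R)
    return best[1]


# --------------------------------------------------------------------- demons


def demons_register(
    fixed: np.ndarray,
    moving: np.ndarray,
    params: DemonsParams | None = None,
    init: DeformationField | None = None,
    ops: GridOps | None = None,
    grid: IcoMesh | None = None,
) -> DeformationField:
    """Spherical diffeomorphic demons between two grid scalar fields.

    Iterates: resample the moving field through the current warp; compute
    the tangent-plane demons velocity u = (f - m_w) g / (|g|^2 + eps
    (f - m_w)^2) with g the surface gradient of the warped moving field;
    cap the step, exponentiate, compose with the running warp; smooth the
    composed tangent field.  Stops on relative metric stagnation, the
    iteration cap, or an unrepairable inverted triangle (the step is
    halved up to 5 times first).
    """
    params = params or DemonsParams()
    if ops is None:
        if grid is None:
            raise ValueError("need ops or grid")
        ops = GridOps(grid)
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    V = ops.grid.vertices
    T = ops.grid.triangles
    h = ops.h_min
    eps = params.epsilon(h)
    cap = 0.5 * h

    if init is None:
        W = V.copy()
    else:
        W = init.warp_positions()
    metric = float(np.mean((ops.locator.interpolate(moving, W) - fixed) ** 2))

    for _ in range(params.max_iterations):
        m_w = ops.locator.interpolate(moving, W)
        e = m_w - fixed
        g = ops.surface_gradient(m_w)
        g2 = np.einsum("ij,ij->i", g, g)
        denom = g2 + eps * e**2
        u = np.where(denom[:, None] > 1e-300, (-e / np.where(denom > 1e-300, denom, 1.0))[:, None] * g, 0.0)
        if params.self_regulated:
            mag = np.linalg.norm(u, axis=1)
            over = mag > cap
            if over.any():
                u[over] *= (cap / mag[over])[:, None]
        u = tangent_project(V, u)

        accepted = False
        for _half in range(6):
            q = exp_map(V, u, check=False)
            Wq = ops.locator.interpolate(W, q)
            Wq /= np.linalg.norm(Wq, axis=1, keepdims=True)
            tau = log_map(V, Wq, max_angle=np.pi - 1e-3)
            smoothed = smooth_deformation(
                DeformationField(ops.grid, tau),
                iterations=params.smoothing_iterations,
                lambda_def=params.lambda_def,
                ops=ops,
            )
            W_new = smoothed.warp_positions()
            if np.all(spherical_orientations(W_new, T) > 0):
                accepted = True
                break
            u = 0.5 * u
        if not accepted:
            log.warning("demons step produced inverted triangles; stopping")
            break
        W = W_new
        new_metric = float(np.mean((ops.locator.interpolate(moving, W) - fixed) ** 2))
        improvement = metric - new_metric
        rel = improvement / metric if metric > 0 else 0.0
        metric = new_metric
        if rel < params.min_metric_change:
            break

    return DeformationField(ops.grid, log_map(V, W))


# ---------------------------------------------------------------- composition


def field_of_rotation(R: Rotation, grid: IcoMesh) -> DeformationField:
    V = grid.vertices
    return DeformationField(grid, log_map(V, R.apply(V)))


def compose(outer, inner: DeformationField, ops: GridOps | None = None) -> DeformationField:
    """Warp composition on the inner field's grid: applying the result is
    applying ``inner`` then ``outer`` (a rotation or another field)."""
    V = inner.base.vertices
    q = inner.warp_positions()
    if isinstance(outer, Rotation):
        target = outer.apply(q)
    elif isinstance(outer, DeformationField):
        loc = (
            ops.locator
            if ops is not None and ops.grid is outer.base
            else SphericalLocator(outer.base.vertices, outer.base.triangles)
        )
        target = loc.interpolate(outer.warp_positions(), q)
        target /= np.linalg.norm(target, axis=1, keepdims=True)
    else:
        raise TypeError("outer must be a Rotation or DeformationField")
    return DeformationField(inner.base, log_map(V, target))


def resample_field(fld: DeformationField, target_grid: IcoMesh) -> DeformationField:
    """Carry a tangent field to another grid: componentwise barycentric
    interpolation followed by tangent-plane projection."""
    if fld.base.level == target_grid.level:
        return DeformationField(target_grid, fld.vectors.copy())
    loc = SphericalLocator(fld.base.vertices, fld.base.triangles)
    vec = loc.interpolate(fld.vectors, target_grid.vertices)
    return DeformationField(target_grid, tangent_project(target_grid.vertices, vec))


# ----------------------------------------------------------------- multi-res


def normalize_level(
    values: np.ndarray,
    rule: str,
    target: np.ndarray | None = None,
) -> np.ndarray:
    if rule == "piecewise_rescale":
        return feat.piecewise_rescale(values)
    if rule == "histogram_match":
        if target is None:
            raise ValueError("histogram_match needs a target field")
        return feat.histogram_match(values, target)
    if rule == "clamp":
        return feat.clamp(values)
    raise ValueError(f"unknown normalization {rule!r}")


def prepare_fixed_level(
    sphere: SphereMesh,
    raw_values: np.ndarray,
    level: ScheduleLevel,
    ops: GridOps,
) -> np.ndarray:
    """Sample a fixed-side (template/subject-as-fixed) feature onto the
    level grid, smooth and self-normalize it (histogram matching has no
    external target on the fixed side, so hull depth falls back to a
    single-sided rescale there)."""
    loc = SphericalLocator(sphere.vertices, sphere.triangles)
    vals = loc.interpolate(np.asarray(raw_values, dtype=float), ops.grid.vertices)
    vals = feat.smooth_scalar(ops.grid, vals, level.lambda_feat)
    if level.normalization == "histogram_match":
        top = vals.max()
        return vals / top if top > 0 else vals
    return normalize_level(vals, level.normalization)


def multires_register(
    moving_sphere: SphereMesh,
    moving_features: dict,
    fixed_level_values: list[np.ndarray],
    schedule: list[ScheduleLevel],
    rot_params: RotationParams | None = None,
    demons_params: DemonsParams | None = None,
) -> tuple[DeformationField, list[dict]]:
    """Coarse-to-fine rotational + demons registration.

    ``fixed_level_values`` holds the fixed (atlas-side) normalized feature
    per schedule level, on that level's grid.  ``moving_features`` maps
    feature names to raw per-vertex fields on ``moving_sphere``.  Returns
    the total deformation on the finest grid (grid vertex -> moving-sphere
    position) and a per-level metric trace.
    """
    rot_params = rot_params or RotationParams()
    demons_params = demons_params or DemonsParams()
    moving_loc = SphericalLocator(moving_sphere.vertices, moving_sphere.triangles)
    tau: DeformationField | None = None
    trace = []
    for level, fixed_vals in zip(schedule, fixed_level_values):
        ops = grid_ops(level.ico_level)
        grid = ops.grid
        if tau is None:
            tau = DeformationField.zero(grid)
        else:
            tau = resample_field(tau, grid)
        W0 = tau.warp_positions()
        raw = np.asarray(moving_features[level.feature], dtype=float)
        m = moving_loc.interpolate(raw, W0)
        m = feat.smooth_scalar(grid, m, level.lambda_feat)
        m = normalize_level(m, level.normalization, target=fixed_vals)
        f = np.asarray(fixed_vals, dtype=float)
        metric0 = float(np.mean((m - f) ** 2))

        R = rotation_register(f, m, rot_params, level_index=level.index, ops=ops)
        psi = field_of_rotation(R, grid)
        psi = demons_register(f, m, demons_params, init=psi, ops=ops)
        # total warp: previous field evaluated at the level-local warp
        q = psi.warp_positions()
        target = ops.locator.interpolate(W0, q)
        target /= np.linalg.norm(target, axis=1, keepdims=True)
        tau = DeformationField(grid, log_map(grid.vertices, target))
        m_final = moving_loc.interpolate(raw, tau.warp_positions())
        m_final = feat.smooth_scalar(grid, m_final, level.lambda_feat)
        m_final = normalize_level(m_final, level.normalization, target=fixed_vals)
        metric1 = float(np.mean((m_final - f) ** 2))
        trace.append(
            {
                "level": level.index,
                "ico_level": level.ico_level,
                "feature": level.feature,
                "initial_metric": metric0,
                "final_metric": metric1,
                "rotation_deg": float(np.degrees(np.linalg.norm(R.as_rotvec()))),
            }
        )
        log.info("level %s: %s", level.index, trace[-1])
    assert tau is not None
    return tau, trace
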