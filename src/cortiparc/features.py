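"""The four per-vertex geometry features driving registration, plus the
per-level smoothing and normalization applied on the icosahedral grids.

Features (AC-PC-aligned RAS millimetre space):

* ``is_distance`` — signed superior-axis offset from the AC-PC line
  (superior positive: temporal pole most negative, superior central sulcus
  most positive).
* ``ap_distance`` — signed anterior-posterior offset from the PC point
  (posterior positive: frontal pole most negative, occipital pole most
  positive).
* ``hull_depth`` — Euclidean distance (mm, >= 0) from each vertex to the
  enclosing convex hull; large in deep grooves such as the insula.
* ``mean_curvature`` — discrete mean curvature (1/mm) from the cotangent
  Laplace-Beltrami operator, convex-outward positive (sphere of radius R
  gives +1/R).

Normalizations: a two-sided piecewise rescale about zero onto [-1, 1]
(keeps the anatomically meaningful zero level fixed), empirical-quantile
histogram matching to a target field, and clamping to [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .mesh import TriangleMesh, vertex_areas

__all__ = [
    "Landmarks",
    "FeatureSet",
    "FEATURE_NAMES",
    "is_distance",
    "ap_distance",
    "hull_depth",
    "mean_curvature",
    "compute_features",
    "smooth_scalar",
    "piecewise_rescale",
    "histogram_match",
    "clamp",
]

FEATURE_NAMES = ("is_distance", "ap_distance", "hull_depth", "mean_curvature")


@dataclass(frozen=True)
class Landmarks:
    """AC and PC landmark coordinates (mm, AC-PC-aligned space)."""

    ac: tuple[float, float, float]
    pc: tuple[float, float, float]

    def __post_init__(self):
        if np.allclose(self.ac, self.pc):
            raise ValueError("AC and PC must be distinct points")

    def to_dict(self) -> dict:
        return {"ac": list(map(float, self.ac)), "pc": list(map(float, self.pc))}

    @classmethod
    def from_dict(cls, d: dict) -> "Landmarks":
        return cls(tuple(d["ac"]), tuple(d["pc"]))


@dataclass
class FeatureSet:
    """The four geometry scalars of one subject, one value per vertex."""

    is_distance: np.ndarray
    ap_distance: np.ndarray
    hull_depth: np.ndarray
    mean_curvature: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in FEATURE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def attach(self, mesh: TriangleMesh) -> None:
        """Write the features onto the mesh as named scalar fields."""
        for name in FEATURE_NAMES:
            mesh.scalar_fields[name] = np.asarray(self[name], dtype=float)


def _acpc_frame(landmarks: Landmarks):
    ac = np.asarray(landmarks.ac, dtype=float)
    pc = np.asarray(landmarks.pc, dtype=float)
    anterior = ac - pc
    anterior /= np.linalg.norm(anterior)
    return ac, pc, anterior


def is_distance(mesh: TriangleMesh, landmarks: Landmarks) -> np.ndarray:
    """Signed superior offset (mm) of each vertex from the AC-PC line.

    The offset is the superior (z) component of the vector from the
    vertex's closest point on the AC-PC line to the vertex.
    """
    ac, pc, anterior = _acpc_frame(landmarks)
    rel = mesh.vertices - pc
    along = rel @ anterior
    perp = rel - along[:, None] * anterior
    return perp[:, 2]


def ap_distance(mesh: TriangleMesh, landmarks: Landmarks) -> np.ndarray:
    """Signed anterior-posterior offset (mm) from the PC point,
    posterior-positive."""
    _, pc, anterior = _acpc_frame(landmarks)
    return (mesh.vertices - pc) @ (-anterior)


def hull_depth(mesh: TriangleMesh) -> np.ndarray:
    """Distance (mm) from each vertex to the enclosing convex hull.

    For points inside a convex polytope the distance to the boundary
    equals the minimum over facets of the distance to the facet plane, so
    the point-to-facet distance is computed exactly from the hull's facet
    equations.  Hull vertices get depth 0.
    """
    hull = ConvexHull(mesh.vertices)
    # facet equations: n.x + d <= 0 inside
    normals = hull.equations[:, :3]
    offsets = hull.equations[:, 3]
    depth = np.full(mesh.n_vertices, np.inf)
    chunk = 1 << 16
    for i in range(0, mesh.n_vertices, chunk):
        pts = mesh.vertices[i : i + chunk]
        d = -(pts @ normals.T + offsets)  # (n, facets), >= 0 inside
        depth[i : i + chunk] = d.min(axis=1)
    return np.clip(depth, 0.0, None)


def mean_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Discrete mean curvature H (1/mm) via the cotangent Laplacian.

    H(v) = ||sum_j (cot a_ij + cot b_ij)(v - v_j)|| / (4 A_v), signed by
    the direction of the mean-curvature normal against the outward vertex
    normal; convex-outward regions are positive (sphere of radius R ->
    +1/R).  Cotangents from near-degenerate triangles are clamped with a
    warning.
    """
    V = mesh.vertices
    T = mesh.triangles
    nv = mesh.n_vertices
    lap = np.zeros((nv, 3))
    wsum_clamped = False
    # accumulate cotangent weights per triangle corner
    for k in range(3):
        i = T[:, k]
        j = T[:, (k + 1) % 3]
        o = T[:, (k + 2) % 3]  # corner opposite edge (i, j)
        u = V[i] - V[o]
        w = V[j] - V[o]
        cross = np.linalg.norm(np.cross(u, w), axis=1)
        small = cross < 1e-12
        if small.any():
            wsum_clamped = True
            cross = np.where(small, 1e-12, cross)
        cot = np.einsum("ij,ij->i", u, w) / cross
        # edge (i, j) gets weight cot/2 from this triangle
        contrib = 0.5 * cot[:, None] * (V[j] - V[i])
        np.add.at(lap, i, contrib)
        np.add.at(lap, j, -contrib)
    if wsum_clamped:
        warnings.warn("near-degenerate triangles: cotangent weights clamped")
    area = vertex_areas(mesh)
    # outward vertex normal: area-weighted triangle normals (CCW winding)
    p = V[T]
    tn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    vn = np.zeros((nv, 3))
    np.add.at(vn, T.ravel(), np.repeat(tn, 3, axis=0).reshape(-1, 3))
    nrm = np.linalg.norm(vn, axis=1)
    vn /= np.where(nrm == 0, 1.0, nrm)[:, None]
    hvec = lap / (2.0 * area[:, None])  # mean-curvature normal, points inward for convex
    mag = np.linalg.norm(hvec, axis=1)
    sign = -np.sign(np.einsum("ij,ij->i", hvec, vn))
    sign[sign == 0] = 1.0
    return sign * mag


def compute_features(mesh: TriangleMesh, landmarks: Landmarks) -> FeatureSet:
    """All four geometry features of a post-processed hemisphere mesh."""
    return FeatureSet(
        is_distance=is_distance(mesh, landmarks),
        ap_distance=ap_distance(mesh, landmarks),
        hull_depth=hull_depth(mesh),
        mean_curvature=mean_curvature(mesh),
    )


def smooth_scalar(mesh, scalar: np.ndarray, lambda_feat: float) -> np.ndarray:
    """One pass of center-vs-1-ring weighted smoothing on a sphere mesh.

    s'(v) = (s(v) + lambda * ringmean(v)) / (1 + lambda); lambda = 0 is
    the identity, larger lambda pulls harder toward the neighborhood mean.
    """
    if lambda_feat < 0:
        raise ValueError("lambda_feat must be >= 0")
    s = np.asarray(scalar, dtype=float)
    if lambda_feat == 0:
        return s.copy()
    tri = mesh.triangles
    nv = len(s)
    e = np.unique(
        np.sort(
            np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1
        ),
        axis=0,
    )
    acc = np.zeros(nv)
    deg = np.zeros(nv)
    np.add.at(acc, e[:, 0], s[e[:, 1]])
    np.add.at(acc, e[:, 1], s[e[:, 0]])
    np.add.at(deg, e[:, 0], 1.0)
    np.add.at(deg, e[:, 1], 1.0)
    ringmean = acc / np.where(deg == 0, 1.0, deg)
    ringmean[deg == 0] = s[deg == 0]
    return (s + lambda_feat * ringmean) / (1.0 + lambda_feat)


def piecewise_rescale(scalar: np.ndarray) -> np.ndarray:
    """Two-sided piecewise-linear rescale about zero onto [-1, 1].

    Negative values are divided by |min|, positive by max, zero stays
    fixed, so the zero level (AC-PC plane / PC coronal plane) is preserved.
    """
    s = np.asarray(scalar, dtype=float)
    lo, hi = s.min(), s.max()
    if lo == 0.0 and hi == 0.0:
        warnings.warn("all-zero field passed to piecewise_rescale")
        return s.copy()
    out = s.copy()
    if lo < 0:
        out[s < 0] = s[s < 0] / abs(lo)
    if hi > 0:
        out[s > 0] = s[s > 0] / hi
    return out


def histogram_match(scalar: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Empirical-quantile matching of one field's histogram to another's.

    Each value is replaced by the target-field quantile at its own
    source-field quantile (averaged ranks on ties; no binning).
    """
    s = np.asarray(scalar, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.size == 0 or t.size == 0:
        raise ValueError("fields must be non-empty")
    if s.max() == s.min():
        warnings.warn("constant source field: mapped to target median")
        return np.full_like(s, np.median(t))
    # averaged ranks across equal values
    _, inv, counts = np.unique(s, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts) - counts
    avg_rank = cum + (counts - 1) / 2.0
    q = avg_rank[inv] / max(len(s) - 1, 1)
    return np.quantile(t, np.clip(q, 0.0, 1.0))


def clamp(scalar: np.ndarray, lo: float = -1.0, hi: float = 1.0) -> np.ndarray:
    """Clamp a field to [lo, hi]."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    return np.clip(np.asarray(scalar, dtype=float), lo, hi)
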