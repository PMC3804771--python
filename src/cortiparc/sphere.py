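"""Bijective spherical parameterization of genus-zero hemisphere meshes.

The construction: (1) split the closed surface into two edge-connected
halves along a plane through the area centroid normal to the longest
principal axis, snapped to mesh edges; (2) smooth the shared boundary
cycle (for its circular arc-length parameterization); (3) map each half
onto the unit disk with the boundary fixed on the circle and interior
vertices solving the uniform-weight (Tutte) convex-combination system;
(4) project each disk onto a hemisphere by inverse stereographic
projection; (5) stitch at the equator (boundary vertices are shared and
both halves use the identical circular boundary, so the equator images
coincide exactly).

For a perfect sphere the composition disk-map + inverse stereographic is
close to the identity, so distortion comes only from the folding pattern;
any flipped spherical triangles after stitching are repaired by local
on-sphere Laplacian relaxation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TriangleMesh, TopologyError, genus

log = logging.getLogger(__name__)

__all__ = [
    "SphereMesh",
    "split_halves",
    "map_half_to_disk",
    "inverse_stereographic",
    "map_to_sphere",
    "spherical_orientations",
]


@dataclass
class SphereMesh:
    """Unit-sphere embedding of a subject mesh (one-to-one by vertex)."""

    vertices: np.ndarray  # (V, 3), all unit norm
    triangles: np.ndarray
    source_ref: str = ""
    scalar_fields: dict = field(default_factory=dict)
    labels: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)


def spherical_orientations(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Signed orientation det[a, b, c] of each spherical triangle; positive
    means consistently outward-oriented."""
    p = vertices[triangles]
    return np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2]))


def _triangle_adjacency_components(triangles, tri_ids):
    """Connected components (by shared edges) of a subset of triangles."""
    idset = set(int(t) for t in tri_ids)
    edge2tri: dict[tuple[int, int], list[int]] = {}
    for t in idset:
        a, b, c = triangles[t]
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            edge2tri.setdefault(key, []).append(t)
    # union-find
    parent = {t: t for t in idset}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ts in edge2tri.values():
        if len(ts) == 2:
            ra, rb = find(ts[0]), find(ts[1])
            if ra != rb:
                parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for t in idset:
        comps.setdefault(find(t), []).append(t)
    return list(comps.values())


def _boundary_cycle(triangles, side):
    """Ordered boundary vertex cycle between side-True and side-False
    triangles, oriented by the True side's winding.  Returns None if the
    boundary is not a single simple cycle."""
    true_dir = set()
    false_dir = set()
    for t, tri in enumerate(triangles):
        a, b, c = tri
        tgt = true_dir if side[t] else false_dir
        tgt.add((a, b))
        tgt.add((b, c))
        tgt.add((c, a))
    boundary = [(u, v) for (u, v) in true_dir if (v, u) in false_dir]
    if not boundary:
        return None
    succ: dict[int, int] = {}
    for u, v in boundary:
        if u in succ:
            return None  # vertex with more than one outgoing boundary edge
        succ[u] = v
    start = min(succ)
    cycle = [start]
    v = succ[start]
    while v != start:
        cycle.append(v)
        if v not in succ or len(cycle) > len(boundary):
            return None
        v = succ[v]
    if len(cycle) != len(boundary):
        return None  # more than one cycle
    return cycle


def split_halves(mesh: TriangleMesh, _check_genus: bool = True):
    """Split a genus-zero mesh into two halves sharing one boundary cycle.

    Returns ``(tri_ids_a, tri_ids_b, boundary_cycle)`` where the cycle is
    ordered by half A's winding.  Tries the longest principal axis first,
    then fallback axes/offsets; raises :class:`TopologyError` if no clean
    single-cycle cut is found.
    """
    if _check_genus and genus(mesh) != 0:
        raise TopologyError("spherical mapping requires a genus-zero mesh")
    V = mesh.vertices
    T = mesh.triangles
    centroid = V.mean(axis=0)
    cov = np.cov((V - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    axes = [evecs[:, 2], evecs[:, 1], evecs[:, 0]]  # descending variance
    # anatomically deterministic axis signs (anterior/superior/right
    # positive), so every subject's positive half is the same half and the
    # sphere maps of a cohort agree up to the residual 1-2 degree rotation
    # the versor stage is designed to absorb
    for k, ax in enumerate(axes):
        for ref in (np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])):
            d = float(ax @ ref)
            if abs(d) > 0.1:
                if d < 0:
                    axes[k] = -ax
                break
    scale = float(np.sqrt(evals[2]))
    tri_centroid_d = None
    for axis in axes:
        d = (V - centroid) @ axis
        for offset in (0.0, 0.25 * scale, -0.25 * scale, 0.5 * scale, -0.5 * scale):
            side_v = d > offset
            tri_score = side_v[T].sum(axis=1)
            side = tri_score >= 2  # majority vote per triangle
            if side.all() or not side.any():
                continue
            # keep the largest edge-connected component on each side
            for flag in (True, False):
                ids = np.nonzero(side == flag)[0]
                comps = _triangle_adjacency_components(T, ids)
                if len(comps) > 1:
                    comps.sort(key=len, reverse=True)
                    for comp in comps[1:]:
                        side[np.asarray(comp)] = not flag
            if side.all() or not side.any():
                continue
            cycle = _boundary_cycle(T, side)
            if cycle is not None:
                # anchor the cycle at its most superior vertex so the
                # circular parameterization origin is anatomically
                # consistent across subjects
                start = int(np.argmax(V[np.asarray(cycle)][:, 2]))
                cycle = cycle[start:] + cycle[:start]
                a_ids = np.nonzero(side)[0]
                b_ids = np.nonzero(~side)[0]
                return a_ids, b_ids, cycle
    raise TopologyError("no clean single-boundary split found on any cut plane")


def _smooth_cycle_positions(points: np.ndarray, iterations: int = 10) -> np.ndarray:
    """Cyclic polyline smoothing used for the arc-length parameterization
    of the boundary on the unit circle (the cut stays on mesh edges)."""
    p = points.copy()
    for _ in range(iterations):
        p = 0.5 * p + 0.25 * (np.roll(p, 1, axis=0) + np.roll(p, -1, axis=0))
    return p


def boundary_angles(mesh: TriangleMesh, cycle: list[int]) -> np.ndarray:
    """Circle angle for each boundary-cycle vertex, spaced proportionally
    to arc length along the smoothed boundary polyline."""
    pts = _smooth_cycle_positions(mesh.vertices[np.asarray(cycle)])
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    return 2.0 * np.pi * cum / seg.sum()


def map_half_to_disk(
    mesh: TriangleMesh,
    tri_ids: np.ndarray,
    cycle: list[int],
    angles: np.ndarray,
) -> dict[int, np.ndarray]:
    """Tutte embedding of one half onto the closed unit disk.

    Boundary-cycle vertices are fixed at (cos a, sin a); interior vertices
    solve the uniform-weight convex-combination linear system, which for a
    convex fixed boundary guarantees a flip-free planar embedding.
    Returns a vertex-id -> (x, y) mapping.
    """
    tris = mesh.triangles[np.asarray(tri_ids)]
    verts = sorted({int(v) for v in tris.ravel()})
    vindex = {v: i for i, v in enumerate(verts)}
    on_boundary = set(cycle)
    interior = [v for v in verts if v not in on_boundary]
    if set(cycle) - set(verts):
        raise ValueError("boundary cycle not contained in the half")
    iindex = {v: i for i, v in enumerate(interior)}
    fixed = np.zeros((len(verts), 2))
    for v, a in zip(cycle, angles):
        fixed[vindex[v]] = (np.cos(a), np.sin(a))
    # adjacency within the half
    nbrs: dict[int, set] = {v: set() for v in verts}
    for a, b, c in tris:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    n = len(interior)
    if n:
        rows, cols, vals = [], [], []
        rhs = np.zeros((n, 2))
        for v in interior:
            i = iindex[v]
            deg = len(nbrs[v])
            rows.append(i)
            cols.append(i)
            vals.append(float(deg))
            for u in nbrs[v]:
                if u in iindex:
                    rows.append(i)
                    cols.append(iindex[u])
                    vals.append(-1.0)
                else:
                    rhs[i] += fixed[vindex[u]]
        A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        try:
            sol = spla.spsolve(A, rhs)
        except Exception as exc:  # pragma: no cover - singular system
            raise RuntimeError(f"singular Tutte system: {exc}") from exc
        sol = np.atleast_2d(sol)
    out = {}
    for v in verts:
        if v in on_boundary:
            out[v] = fixed[vindex[v]]
        else:
            out[v] = sol[iindex[v]]
    return out


def inverse_stereographic(disk_coords: np.ndarray, hemisphere: str) -> np.ndarray:
    """Inverse stereographic projection of unit-disk points onto a unit
    hemisphere: (x, y) -> (2x, 2y, +-(1 - r^2)) / (1 + r^2).  The disk
    center maps to the pole and the unit circle to the equator."""
    xy = np.atleast_2d(np.asarray(disk_coords, dtype=float))
    r2 = np.einsum("ij,ij->i", xy, xy)
    denom = 1.0 + r2
    z = (1.0 - r2) / denom
    if hemisphere == "south":
        z = -z
    elif hemisphere != "north":
        raise ValueError("hemisphere must be 'north' or 'south'")
    return np.column_stack([2.0 * xy[:, 0] / denom, 2.0 * xy[:, 1] / denom, z])


def _repair_flips(verts: np.ndarray, triangles: np.ndarray, max_iter: int = 50):
    """Local spherical Laplacian relaxation restricted to flipped-triangle
    neighborhoods, reprojecting to the sphere each step."""
    from .mesh import vertex_adjacency

    adj = None
    for _ in range(max_iter):
        orient = spherical_orientations(verts, triangles)
        bad = orient <= 0
        if not bad.any():
            return verts, 0
        if adj is None:
            adj = vertex_adjacency(triangles, len(verts))
        move = np.unique(triangles[bad].ravel())
        for v in move:
            nb = adj[v]
            p = 0.5 * verts[v] + 0.5 * verts[nb].mean(axis=0)
            n = np.linalg.norm(p)
            if n > 0:
                verts[v] = p / n
    orient = spherical_orientations(verts, triangles)
    return verts, int((orient <= 0).sum())


def map_to_sphere(mesh: TriangleMesh, source_ref: str = "") -> SphereMesh:
    """Map a closed genus-zero mesh bijectively onto the unit sphere.

    Vertex/triangle counts and indices are preserved; scalar and label
    fields carry over by vertex identity.  Raises if flipped spherical
    triangles persist after local relaxation.
    """
    a_ids, b_ids, cycle = split_halves(mesh)
    angles = boundary_angles(mesh, cycle)
    disk_a = map_half_to_disk(mesh, a_ids, cycle, angles)
    disk_b = map_half_to_disk(mesh, b_ids, cycle, angles)
    unit = np.zeros((mesh.n_vertices, 3))
    ids_a = np.fromiter(disk_a.keys(), dtype=np.int64)
    unit[ids_a] = inverse_stereographic(
        np.array([disk_a[v] for v in ids_a]), "north"
    )
    ids_b = np.fromiter(disk_b.keys(), dtype=np.int64)
    south = inverse_stereographic(np.array([disk_b[v] for v in ids_b]), "south")
    # boundary vertices already written by half A; equator images coincide
    interior_b = ~np.isin(ids_b, np.asarray(cycle))
    unit[ids_b[interior_b]] = south[interior_b]
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    unit, n_bad = _repair_flips(unit, mesh.triangles)
    if n_bad:
        raise TopologyError(
            f"spherical map has {n_bad} flipped triangles after relaxation"
        )
    return SphereMesh(
        vertices=unit,
        triangles=mesh.triangles.copy(),
        source_ref=source_ref,
        scalar_fields={k: v.copy() for k, v in mesh.scalar_fields.items()},
        labels=None if mesh.labels is None else mesh.labels.copy(),
    )
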