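"""Triangle-mesh data model, topology checks, and surface post-processing.

The whole pipeline is carried by :class:`TriangleMesh`: an embedded
triangulated 2-manifold with named per-vertex scalar fields and an optional
per-vertex integer label field.  Pipeline inputs are closed genus-zero
hemisphere surfaces in AC-PC-aligned millimetre coordinates
(right-anterior-superior axis order), with counter-clockwise triangle
winding viewed from outside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "TopologyError",
    "genus",
    "edge_set",
    "vertex_areas",
    "triangle_areas",
    "laplacian_smooth",
    "vertex_adjacency",
    "vertex_triangle_map",
]


class TopologyError(ValueError):
    """Raised when a mesh violates a required topological property."""


@dataclass
class TriangleMesh:
    """An indexed triangle set with per-vertex attributes.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex positions in mm.
    triangles : (F, 3) int array
        Vertex index triplets with consistent counter-clockwise winding
        viewed from outside the surface.
    scalar_fields : dict of str -> (V,) float array
        Named per-vertex scalar fields.
    labels : (V,) int array or None
        Optional per-vertex region ids.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    scalar_fields: dict = field(default_factory=dict)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (F, 3)")
        nv = len(self.vertices)
        for name, f in self.scalar_fields.items():
            f = np.asarray(f, dtype=float)
            if f.shape != (nv,):
                raise ValueError(
                    f"scalar field {name!r} has {f.shape} values, expected ({nv},)"
                )
            self.scalar_fields[name] = f
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (nv,):
                raise ValueError("label field must have one value per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            {k: v.copy() for k, v in self.scalar_fields.items()},
            None if self.labels is None else self.labels.copy(),
        )

    def validate_closed(self) -> None:
        """Check that every edge is shared by exactly two consistently
        oriented triangles; raise :class:`TopologyError` otherwise."""
        directed = {}
        for t, (a, b, c) in enumerate(self.triangles):
            for u, v in ((a, b), (b, c), (c, a)):
                if (u, v) in directed:
                    raise TopologyError(
                        f"directed edge ({u},{v}) appears twice: inconsistent "
                        f"orientation or non-manifold at triangle {t}"
                    )
                directed[(u, v)] = t
        for (u, v) in directed:
            if (v, u) not in directed:
                raise TopologyError(f"boundary or non-manifold edge ({u},{v})")


def edge_set(triangles: np.ndarray) -> np.ndarray:
    """Unique undirected edges as a (E, 2) sorted-index array."""
    e = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def genus(mesh: TriangleMesh) -> int:
    """Genus of a closed manifold mesh via the Euler characteristic.

    g = (2 - V + E - F) / 2; a genus-zero surface is a topological sphere.
    """
    mesh.validate_closed()
    V = mesh.n_vertices
    F = mesh.n_triangles
    E = len(edge_set(mesh.triangles))
    chi = V - E + F
    g2 = 2 - chi
    if g2 % 2:
        raise TopologyError(f"odd Euler defect (chi={chi}); not a closed surface")
    return g2 // 2


def triangle_areas(mesh: TriangleMesh) -> np.ndarray:
    p = mesh.vertices[mesh.triangles]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex surface area (mm^2): one third of each incident triangle.

    The 1/3 rule makes region areas well defined at label borders where a
    triangle's corners disagree, and conserves total area exactly:
    sum(vertex_areas) == sum(triangle_areas).
    """
    ta = triangle_areas(mesh)
    if np.any(ta == 0.0):
        warnings.warn("degenerate zero-area triangle(s); they contribute 0 area")
    va = np.zeros(mesh.n_vertices)
    np.add.at(va, mesh.triangles.ravel(), np.repeat(ta / 3.0, 3))
    return va


def vertex_adjacency(triangles: np.ndarray, n_vertices: int) -> list[np.ndarray]:
    """1-ring neighbor indices for each vertex."""
    nbr = [set() for _ in range(n_vertices)]
    for a, b, c in triangles:
        nbr[a].update((b, c))
        nbr[b].update((a, c))
        nbr[c].update((a, b))
    return [np.fromiter(sorted(s), dtype=np.int64) for s in nbr]


def vertex_triangle_map(triangles: np.ndarray, n_vertices: int) -> list[np.ndarray]:
    """Incident triangle ids for each vertex."""
    v2t = [[] for _ in range(n_vertices)]
    for t, (a, b, c) in enumerate(triangles):
        v2t[a].append(t)
        v2t[b].append(t)
        v2t[c].append(t)
    return [np.asarray(t, dtype=np.int64) for t in v2t]


def laplacian_smooth(
    mesh: TriangleMesh, iterations: int = 5, relaxation: float = 0.1
) -> TriangleMesh:
    """Uniform-weight Laplacian smoothing.

    Per iteration each vertex moves by ``relaxation`` times the offset from
    itself to the centroid of its 1-ring neighbors.  Connectivity and all
    attached fields are unchanged.  Defaults are the pipeline's surface
    post-processing settings (5 iterations, relaxation 0.1).
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not (0.0 <= relaxation <= 1.0):
        raise ValueError("relaxation must be in [0, 1]")
    out = mesh.copy()
    if iterations == 0:
        return out
    nv = mesh.n_vertices
    tri = mesh.triangles
    # neighbor sums via edge scatter-add; degree per vertex
    e = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    deg = np.zeros(nv)
    np.add.at(deg, e[:, 0], 1.0)
    np.add.at(deg, e[:, 1], 1.0)
    isolated = deg == 0
    if isolated.any():
        log.warning("%d isolated vertices left unmoved", int(isolated.sum()))
    deg_safe = np.where(isolated, 1.0, deg)
    pos = out.vertices
    for _ in range(iterations):
        acc = np.zeros_like(pos)
        np.add.at(acc, e[:, 0], pos[e[:, 1]])
        np.add.at(acc, e[:, 1], pos[e[:, 0]])
        centroid = acc / deg_safe[:, None]
        move = relaxation * (centroid - pos)
        move[isolated] = 0.0
        pos = pos + move
    out.vertices = pos
    return out
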