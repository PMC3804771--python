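"""Synthetic cortex-like cohorts with known labels and known warps.

Real pipeline inputs are genus-zero hemisphere surfaces with manual
parcellations, which cannot ship with the package; the generator emulates
the properties the pipeline actually consumes: a closed genus-zero mesh
with sulcus/gyrus-like radial undulations (giving hull-depth and
curvature structure), a 24-region + unlabeled-cap parcellation, AC/PC
landmarks on the centerline, and cohort members that are smooth
tangential diffeomorphic warps of a common template plus small radial
noise.  Because the warps are tangential-only, the vertexwise
ground-truth correspondence between any subject and the template is
exact, which is what makes registration-recovery and end-to-end Dice
tests possible without MRI data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .features import Landmarks
from .icosphere import build_icosphere, shortest_edge_length
from .mesh import TriangleMesh
from .registration import exp_map, tangent_project
from .sphere import spherical_orientations

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticSubject",
    "make_template",
    "make_subject",
    "make_cohort",
    "random_tangent_warp",
    "smoothing_iterations_for_scale",
]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions of a synthetic cohort.

    Angular quantities are radians on the unit direction sphere; the warp
    magnitude is a fraction of the IC4 shortest edge length, kept at the
    injectivity-safe 0.5 so single-step exponentiation cannot fold the
    mesh.
    """

    seed: int = 0
    n_subjects: int = 8
    mesh_level: int = 5  # icosphere subdivision of the template mesh
    base_radius: float = 60.0  # mm, hemisphere scale
    n_bumps: int = 40
    bump_width: float = 0.25  # rad
    bump_amplitude: float = 0.05  # fraction of base radius
    warp_fraction: float = 0.5  # of the IC4 shortest edge length
    warp_scale: float = 0.6  # rad, correlation scale of the warp field
    noise_sd: float = 0.05  # mm radial noise
    n_regions: int = 24
    cap_angle: float = 0.45  # rad, unlabeled polar cap around -x

    def __post_init__(self):
        if self.bump_amplitude < 0 or self.noise_sd < 0 or self.warp_fraction < 0:
            raise ValueError("magnitudes must be >= 0")
        if self.warp_fraction > 0.5:
            raise ValueError("warp_fraction beyond the injectivity-safe bound 0.5")


@dataclass
class SyntheticSubject:
    mesh: TriangleMesh
    landmarks: Landmarks
    directions: np.ndarray  # unit parameter direction of each vertex
    true_warp: np.ndarray | None = None  # tangent field applied to the template
    subject_id: str = ""


def _ring_smooth(triangles: np.ndarray, values: np.ndarray, iterations: int) -> np.ndarray:
    """Iterated half-blend with the 1-ring mean (sparse matvec form)."""
    import scipy.sparse as sp

    nv = len(values)
    e = np.unique(
        np.sort(
            np.concatenate(
                [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
            ),
            axis=1,
        ),
        axis=0,
    )
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(nv, nv))
    deg = np.asarray(A.sum(axis=1)).ravel()
    Dinv = sp.diags(1.0 / np.where(deg == 0, 1.0, deg))
    M = Dinv @ A
    v = values.copy()
    for _ in range(iterations):
        v = 0.5 * v + 0.5 * (M @ v)
    return v


def _fibonacci_directions(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _radius_field(directions: np.ndarray, spec: SyntheticCohortSpec, rng) -> np.ndarray:
    r = np.full(len(directions), spec.base_radius)
    if spec.n_bumps == 0 or spec.bump_amplitude == 0:
        return r
    centers = rng.normal(size=(spec.n_bumps, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    signs = np.where(np.arange(spec.n_bumps) % 2 == 0, 1.0, -1.0)
    ang = np.arccos(np.clip(directions @ centers.T, -1.0, 1.0))
    bumps = np.exp(-(ang**2) / (2 * spec.bump_width**2)) @ signs
    return spec.base_radius * (1.0 + spec.bump_amplitude * bumps)


def _voronoi_labels(directions: np.ndarray, spec: SyntheticCohortSpec, rng) -> np.ndarray:
    seeds = _fibonacci_directions(spec.n_regions)
    # deterministic random orientation of the seed constellation
    from scipy.spatial.transform import Rotation

    seeds = Rotation.random(random_state=np.random.RandomState(spec.seed)).apply(seeds)
    labels = np.argmax(directions @ seeds.T, axis=1) + 1
    cap_axis = np.array([-1.0, 0.0, 0.0])
    in_cap = np.arccos(np.clip(directions @ cap_axis, -1, 1)) < spec.cap_angle
    labels[in_cap] = 0
    return labels.astype(np.int64)


def make_template(spec: SyntheticCohortSpec) -> SyntheticSubject:
    """Deterministic template: icosphere directions with bump-modulated
    radius, nearest-seed spherical-Voronoi labels plus an unlabeled polar
    cap, and AC/PC landmarks on the centerline."""
    rng = np.random.default_rng(spec.seed)
    ico = build_icosphere(spec.mesh_level)
    directions = ico.vertices.copy()
    radius = _radius_field(directions, spec, rng)
    mesh = TriangleMesh(radius[:, None] * directions, ico.triangles.copy())
    mesh.labels = _voronoi_labels(directions, spec, rng)
    landmarks = Landmarks(
        ac=(0.0, 0.25 * spec.base_radius, -0.15 * spec.base_radius),
        pc=(0.0, 0.0, -0.15 * spec.base_radius),
    )
    return SyntheticSubject(
        mesh=mesh,
        landmarks=landmarks,
        directions=directions,
        subject_id=f"template-seed{spec.seed}",
    )


def smoothing_iterations_for_scale(scale: float, edge_length: float) -> int:
    """Half-blend ring-smoothing iterations that give a random field an
    angular correlation scale of roughly ``scale`` radians on a mesh with
    the given typical edge length (diffusion-time calibration)."""
    return max(1, int(np.ceil(4.0 * (scale / edge_length) ** 2)))


def random_tangent_warp(
    directions: np.ndarray,
    triangles: np.ndarray,
    rng,
    magnitude: float,
    scale: float,
) -> np.ndarray:
    """Smooth random tangential field of the given max magnitude and
    angular correlation scale on a sphere mesh."""
    edges = np.linalg.norm(
        directions[triangles[:, 0]] - directions[triangles[:, 1]], axis=1
    )
    iters = smoothing_iterations_for_scale(scale, float(np.median(edges)))
    raw = rng.normal(size=directions.shape)
    smooth = _ring_smooth(triangles, raw, iters)
    tang = tangent_project(directions, smooth)
    top = np.linalg.norm(tang, axis=1).max()
    if top == 0:
        return tang
    return tang * (magnitude / top)


def make_subject(
    template: SyntheticSubject,
    spec: SyntheticCohortSpec,
    seed: int,
    subject_id: str = "",
) -> SyntheticSubject:
    """A cohort member: the template anatomy carried through a smooth
    random tangential warp of the parameter sphere plus radial noise.

    Vertex i of the subject corresponds exactly to vertex i of the
    template (anatomy, labels and features all ride the warp), and the
    generating tangent field is returned for recovery tests.  If a drawn
    warp inverts a triangle its magnitude is halved and redrawn.
    """
    rng = np.random.default_rng(seed)
    h_ic4 = shortest_edge_length(build_icosphere(4))
    magnitude = spec.warp_fraction * h_ic4
    tri = template.mesh.triangles
    for attempt in range(8):
        warp = random_tangent_warp(
            template.directions, tri, rng, magnitude, spec.warp_scale
        )
        q = exp_map(template.directions, warp, check=False)
        if np.all(spherical_orientations(q, tri) > 0):
            break
        magnitude *= 0.5
        log.warning("warp inverted a triangle; retrying with magnitude %.4g", magnitude)
    else:
        raise RuntimeError("could not draw an inversion-free warp")
    radius = np.linalg.norm(template.mesh.vertices, axis=1)
    noise = rng.normal(scale=spec.noise_sd, size=len(radius)) if spec.noise_sd else 0.0
    mesh = TriangleMesh((radius + noise)[:, None] * q, tri.copy())
    mesh.labels = template.mesh.labels.copy()
    return SyntheticSubject(
        mesh=mesh,
        landmarks=template.landmarks,
        directions=q,
        true_warp=warp,
        subject_id=subject_id or f"subject-seed{seed}",
    )


def make_cohort(spec: SyntheticCohortSpec) -> tuple[SyntheticSubject, list[SyntheticSubject]]:
    """Template plus ``n_subjects`` warped cohort members, fully
    reproducible from the spec (subject k uses seed ``spec.seed*1000+k+1``)."""
    template = make_template(spec)
    subjects = [
        make_subject(template, spec, seed=spec.seed * 1000 + k + 1, subject_id=f"s{k:02d}")
        for k in range(spec.n_subjects)
    ]
    return template, subjects
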