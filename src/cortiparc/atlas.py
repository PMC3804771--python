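"""Hemisphere surface atlases: population-mean geometry features per
registration level plus greatest-probability labels, and atlas-based
parcellation of new subjects.

Atlas building registers every training subject to a chosen template
surface, averages the normalized geometry features per grid vertex at
every schedule level (the template contributes its own features and
labels as one of the cohort), and assigns each finest-grid vertex the
most frequent warped training label (ties resolved toward the lowest
label id).  Parcellation registers the atlas onto a new subject's sphere
(same engine, fixed/moving roles swapped) and carries the atlas labels
through the correspondence onto every subject vertex.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import features as feat
from .features import FEATURE_NAMES, Landmarks, compute_features
from .icosphere import SphericalLocator, build_icosphere, resample_label
from .labels import LabelTable, cortical_24_table
from .mesh import TriangleMesh
from .registration import (
    DeformationField,
    DemonsParams,
    RotationParams,
    ScheduleLevel,
    default_schedule,
    grid_ops,
    multires_register,
    normalize_level,
    tangent_project,
    exp_map,
)
from .sphere import SphereMesh, map_to_sphere

log = logging.getLogger(__name__)

__all__ = [
    "Atlas",
    "Subject",
    "build_atlas",
    "parcellate",
    "subject_from_mesh",
    "majority_vote",
]


def majority_vote(vote_matrix: np.ndarray) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Per-vertex most frequent label across voters (rows), with ties
    resolved toward the lowest label id; returns the winners and the
    per-label probability fields (probabilities sum to 1 per vertex)."""
    votes = np.asarray(vote_matrix, dtype=np.int64)
    uniq = np.unique(votes)
    counts = np.stack([(votes == lab).sum(axis=0) for lab in uniq])
    winner = uniq[np.argmax(counts, axis=0)]
    probs = {int(lab): counts[i] / votes.shape[0] for i, lab in enumerate(uniq)}
    return winner.astype(np.int64), probs


@dataclass
class Subject:
    """One subject's spherical representation: unit sphere mesh carrying
    the raw geometry features and (optionally) per-vertex labels."""

    sphere: SphereMesh
    features: dict
    labels: np.ndarray | None = None
    subject_id: str = ""


def subject_from_mesh(
    mesh: TriangleMesh, landmarks: Landmarks, subject_id: str = ""
) -> Subject:
    """Full per-subject preprocessing: geometry features on the cortical
    mesh, then the bijective spherical map (fields ride along by vertex
    identity)."""
    fs = compute_features(mesh, landmarks)
    fs.attach(mesh)
    sphere = map_to_sphere(mesh, source_ref=subject_id)
    return Subject(
        sphere=sphere,
        features={name: fs[name] for name in FEATURE_NAMES},
        labels=None if mesh.labels is None else mesh.labels.copy(),
        subject_id=subject_id,
    )


@dataclass
class Atlas:
    """Icosahedral surface atlas.

    ``mean_features[k]`` is the mean normalized feature of schedule level
    k on that level's grid; ``labels`` and ``label_probabilities`` live on
    the finest schedule grid.
    """

    schedule: list[ScheduleLevel]
    mean_features: list[np.ndarray]
    labels: np.ndarray
    label_probabilities: dict[int, np.ndarray]
    label_table: LabelTable
    provenance: dict = field(default_factory=dict)

    @property
    def finest_level(self) -> int:
        return self.schedule[-1].ico_level

    def save(self, directory: str) -> None:
        from .io import write_mesh

        os.makedirs(directory, exist_ok=True)
        meta = {
            "schedule": [
                [l.index, l.ico_level, l.feature, l.normalization, l.lambda_feat]
                for l in self.schedule
            ],
            "label_table": self.label_table.to_dict(),
            "provenance": self.provenance,
        }
        with open(os.path.join(directory, "atlas.json"), "w") as f:
            json.dump(meta, f, indent=1)
        for lvl, vals in zip(self.schedule, self.mean_features):
            grid = build_icosphere(lvl.ico_level)
            m = TriangleMesh(grid.vertices, grid.triangles)
            m.scalar_fields[f"mean_{lvl.feature}"] = vals
            write_mesh(m, os.path.join(directory, f"level{lvl.index}_ic{lvl.ico_level}.vtk"))
        grid = build_icosphere(self.finest_level)
        m = TriangleMesh(grid.vertices, grid.triangles, labels=self.labels)
        for lab, p in self.label_probabilities.items():
            m.scalar_fields[f"prob_{lab}"] = p
        write_mesh(m, os.path.join(directory, "labels.vtk"))

    @classmethod
    def load(cls, directory: str) -> "Atlas":
        from .io import read_mesh

        with open(os.path.join(directory, "atlas.json")) as f:
            meta = json.load(f)
        schedule = [ScheduleLevel(*row) for row in meta["schedule"]]
        mean_features = []
        for lvl in schedule:
            m = read_mesh(os.path.join(directory, f"level{lvl.index}_ic{lvl.ico_level}.vtk"))
            mean_features.append(np.asarray(m.scalar_fields[f"mean_{lvl.feature}"], dtype=float))
        lab_mesh = read_mesh(os.path.join(directory, "labels.vtk"))
        probs = {
            int(name.split("_", 1)[1]): np.asarray(vals, dtype=float)
            for name, vals in lab_mesh.scalar_fields.items()
            if name.startswith("prob_")
        }
        return cls(
            schedule=schedule,
            mean_features=mean_features,
            labels=lab_mesh.labels,
            label_probabilities=probs,
            label_table=LabelTable.from_dict(meta["label_table"]),
            provenance=meta.get("provenance", {}),
        )


def _prepare_fixed(
    sphere: SphereMesh,
    raw: np.ndarray,
    level: ScheduleLevel,
    target: np.ndarray | None = None,
):
    """Sample, smooth and normalize a fixed-side feature on a level grid.

    When a target is given, histogram matching uses it (the
    subject-matched-to-atlas direction); otherwise hull depth falls back
    to a max-rescale so the template side is still in [0, 1].
    """
    ops = grid_ops(level.ico_level)
    loc = SphericalLocator(sphere.vertices, sphere.triangles)
    vals = loc.interpolate(np.asarray(raw, dtype=float), ops.grid.vertices)
    vals = feat.smooth_scalar(ops.grid, vals, level.lambda_feat)
    if level.normalization == "histogram_match" and target is None:
        top = vals.max()
        return vals / top if top > 0 else vals
    return normalize_level(vals, level.normalization, target=target)


def _warped_normalized_features(
    subject: Subject,
    tau: DeformationField,
    schedule: list[ScheduleLevel],
    fixed_level_values: list[np.ndarray],
) -> list[np.ndarray]:
    """Subject features carried into atlas space at each level grid."""
    from .registration import resample_field

    out = []
    loc = SphericalLocator(subject.sphere.vertices, subject.sphere.triangles)
    for lvl, fixed_vals in zip(schedule, fixed_level_values):
        ops = grid_ops(lvl.ico_level)
        tau_l = resample_field(tau, ops.grid)
        W = tau_l.warp_positions()
        vals = loc.interpolate(np.asarray(subject.features[lvl.feature], dtype=float), W)
        vals = feat.smooth_scalar(ops.grid, vals, lvl.lambda_feat)
        vals = normalize_level(vals, lvl.normalization, target=fixed_vals)
        out.append(vals)
    return out


def build_atlas(
    template: Subject,
    training: list[Subject],
    schedule: list[ScheduleLevel] | None = None,
    rot_params: RotationParams | None = None,
    demons_params: DemonsParams | None = None,
    label_table: LabelTable | None = None,
) -> Atlas:
    """Build a surface atlas from a template and training subjects.

    The template's features and labels are included in the mean/vote.
    Subjects whose registration fails are excluded with a logged reason;
    if all fail, an error is raised.
    """
    schedule = schedule or default_schedule()
    label_table = label_table or cortical_24_table()
    if template.labels is None:
        raise ValueError("template must carry labels")

    fixed_vals = [
        _prepare_fixed(template.sphere, template.features[lvl.feature], lvl)
        for lvl in schedule
    ]
    feature_sums = [v.copy() for v in fixed_vals]
    n_contrib = 1

    finest = grid_ops(schedule[-1].ico_level).grid
    votes = [resample_label(template.sphere, template.labels, finest)]
    used_ids = [template.subject_id or "template"]
    for subj in training:
        if subj.subject_id == template.subject_id and subj is not template:
            continue
        if subj is template:
            continue
        try:
            tau, trace = multires_register(
                subj.sphere, subj.features, fixed_vals, schedule,
                rot_params, demons_params,
            )
        except Exception as exc:
            log.warning("subject %r failed registration: %s", subj.subject_id, exc)
            continue
        for k, vals in enumerate(
            _warped_normalized_features(subj, tau, schedule, fixed_vals)
        ):
            feature_sums[k] += vals
        if subj.labels is not None:
            loc = SphericalLocator(subj.sphere.vertices, subj.sphere.triangles)
            votes.append(loc.nearest_corner_label(subj.labels, tau.warp_positions()))
        n_contrib += 1
        used_ids.append(subj.subject_id)
    if n_contrib == 1 and training:
        raise RuntimeError("all training subjects failed registration")

    mean_features = [s / n_contrib for s in feature_sums]
    winner, probs = majority_vote(np.stack(votes))
    params_hash = hashlib.sha256(
        json.dumps(
            [[l.index, l.ico_level, l.feature, l.normalization, l.lambda_feat] for l in schedule]
        ).encode()
    ).hexdigest()[:12]
    return Atlas(
        schedule=schedule,
        mean_features=mean_features,
        labels=winner.astype(np.int64),
        label_probabilities=probs,
        label_table=label_table,
        provenance={
            "template": template.subject_id or "template",
            "training": used_ids,
            "parameter_hash": params_hash,
        },
    )


def parcellate(
    subject: Subject | TriangleMesh,
    atlas: Atlas,
    landmarks: Landmarks | None = None,
    rot_params: RotationParams | None = None,
    demons_params: DemonsParams | None = None,
) -> np.ndarray:
    """Label every vertex of a subject surface from the atlas.

    The subject plays the fixed role; the atlas sphere (finest grid
    carrying the mean features) is the moving surface mapped onto it.
    Each subject vertex is carried through the recovered correspondence
    into atlas space and takes the nearest atlas label.
    """
    if isinstance(subject, TriangleMesh):
        if landmarks is None:
            raise ValueError("landmarks required when passing a raw mesh")
        subject = subject_from_mesh(subject, landmarks)
    schedule = atlas.schedule
    finest_ops = grid_ops(atlas.finest_level)
    atlas_sphere = SphereMesh(
        vertices=finest_ops.grid.vertices,
        triangles=finest_ops.grid.triangles,
        source_ref="atlas",
    )
    # atlas mean features (stored per level) resampled onto the finest grid
    atlas_features = {}
    for lvl, vals in zip(schedule, atlas.mean_features):
        ops = grid_ops(lvl.ico_level)
        atlas_features[lvl.feature] = ops.locator.interpolate(
            vals, finest_ops.grid.vertices
        )
    # fixed side: subject features, histogram-matched toward the atlas
    fixed_vals = [
        _prepare_fixed(
            subject.sphere,
            subject.features[lvl.feature],
            lvl,
            target=vals if lvl.normalization == "histogram_match" else None,
        )
        for lvl, vals in zip(schedule, atlas.mean_features)
    ]
    tau, trace = multires_register(
        atlas_sphere, atlas_features, fixed_vals, schedule, rot_params, demons_params
    )
    # evaluate the grid warp at each subject sphere vertex
    P = subject.sphere.vertices
    vec = finest_ops.locator.interpolate(tau.vectors, P)
    vec = tangent_project(P, vec)
    atlas_pos = exp_map(P, vec, check=False)
    labels = finest_ops.locator.nearest_corner_label(atlas.labels, atlas_pos)
    return labels
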