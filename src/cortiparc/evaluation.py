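"""Parcellation validity metrics: surface-area Dice per region and
cross-cohort per-vertex accuracy.

Dice is computed on labeled surface area, D = 2|A ∩ B| / (|A| + |B|),
with region areas accumulated from per-vertex areas (each vertex owns one
third of its incident triangles), so areas are well defined at region
borders where a triangle's corners disagree.  Vertex accuracy is the
percentage of test subjects whose automated label matches the
gold-standard label at a grid vertex, summarized in ten 10-point bins
(the value 100 counts in the top bin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .labels import LabelTable
from .mesh import TriangleMesh, vertex_areas

__all__ = [
    "RegionOverlap",
    "OverlapReport",
    "AccuracyMap",
    "dice_by_region",
    "vertex_accuracy",
    "consolidate_labels",
]


@dataclass(frozen=True)
class RegionOverlap:
    label_id: int
    dice: float | None  # None when the region is absent from both
    area_a: float
    area_b: float
    shared_area: float


@dataclass
class OverlapReport:
    per_region: list[RegionOverlap]
    subject_id: str = ""

    def mean_dice(self, include_unlabeled: bool = True, unlabeled_id: int = 0) -> float:
        vals = [
            r.dice
            for r in self.per_region
            if r.dice is not None
            and (include_unlabeled or r.label_id != unlabeled_id)
        ]
        return float(np.mean(vals)) if vals else float("nan")

    def dice_of(self, label_id: int) -> float | None:
        for r in self.per_region:
            if r.label_id == label_id:
                return r.dice
        raise KeyError(label_id)

    def to_tsv(self) -> str:
        lines = ["region\tdice\tarea_a\tarea_b\tshared_area"]
        for r in self.per_region:
            d = "NA" if r.dice is None else f"{r.dice:.4f}"
            lines.append(
                f"{r.label_id}\t{d}\t{r.area_a:.4f}\t{r.area_b:.4f}\t{r.shared_area:.4f}"
            )
        return "\n".join(lines) + "\n"


def dice_by_region(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    mesh: TriangleMesh,
    table: LabelTable,
    subject_id: str = "",
) -> OverlapReport:
    """Per-region surface-area Dice between two labelings of one mesh.

    Regions absent from both labelings get a missing (None) Dice and are
    excluded from the mean; labels outside the table are still reported,
    with a warning.
    """
    a = np.asarray(labels_a, dtype=np.int64)
    b = np.asarray(labels_b, dtype=np.int64)
    if a.shape != b.shape or len(a) != mesh.n_vertices:
        raise ValueError("label fields must both match the mesh vertex count")
    va = vertex_areas(mesh)
    present = np.union1d(np.unique(a), np.unique(b))
    extraneous = [int(l) for l in present if l not in table]
    if extraneous:
        warnings.warn(f"labels not in table: {extraneous}")
    report = []
    for lab in sorted(set(table.ids) | set(int(l) for l in present)):
        in_a = a == lab
        in_b = b == lab
        area_a = float(va[in_a].sum())
        area_b = float(va[in_b].sum())
        shared = float(va[in_a & in_b].sum())
        if area_a == 0.0 and area_b == 0.0:
            dice = None
        else:
            dice = 2.0 * shared / (area_a + area_b)
        report.append(RegionOverlap(int(lab), dice, area_a, area_b, shared))
    return OverlapReport(report, subject_id=subject_id)


@dataclass
class AccuracyMap:
    """Per-vertex percentage agreement across a testing cohort."""

    accuracy: np.ndarray  # (V,) in [0, 100]
    histogram: np.ndarray  # (10,) counts per [0,10), ..., [90,100] bin

    @property
    def fraction_above(self):
        def f(threshold: float) -> float:
            return float(np.mean(self.accuracy > threshold))

        return f


def vertex_accuracy(gold: list[np.ndarray], auto: list[np.ndarray]) -> AccuracyMap:
    """Fraction (as a percentage) of subject pairs agreeing at each vertex.

    All label arrays must live on the same grid; the histogram uses ten
    10-point bins labeled by their minimum, with 100 in the top bin.
    """
    if len(gold) == 0 or len(gold) != len(auto):
        raise ValueError("need matching non-empty gold/auto lists")
    n = len(gold[0])
    for g, a in zip(gold, auto):
        if len(g) != n or len(a) != n:
            raise ValueError("mismatched grids across subjects")
    agree = np.zeros(n)
    for g, a in zip(gold, auto):
        agree += np.asarray(g) == np.asarray(a)
    acc = 100.0 * agree / len(gold)
    bins = np.minimum((acc // 10).astype(int), 9)
    hist = np.bincount(bins, minlength=10)
    return AccuracyMap(accuracy=acc, histogram=hist)


def consolidate_labels(labels: np.ndarray, mapping: dict[int, int]) -> np.ndarray:
    """Apply a many-to-one label consolidation (e.g. merging the rostral /
    intermediate / caudal thirds of a gyrus into one region)."""
    labs = np.asarray(labels, dtype=np.int64)
    present = np.unique(labs)
    missing = [int(l) for l in present if l not in mapping]
    if missing:
        raise KeyError(f"labels without a consolidation entry: {missing}")
    out = labs.copy()
    for src, dst in mapping.items():
        out[labs == src] = dst
    return out
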