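"""Region label tables for cortical parcellation schemes.

A :class:`LabelTable` maps integer region ids to abbreviations and full
names, with exactly one id reserved for the unlabeled (non-cortical) area.
Two schemes ship with the package: the 24-region-per-hemisphere scheme the
pipeline was designed around, and the 34-region FreeSurfer/Desikan scheme,
which is supported purely as an alternative table.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class LabelEntry:
    label_id: int
    abbreviation: str
    name: str


@dataclass
class LabelTable:
    entries: list[LabelEntry]
    unlabeled_id: int = 0

    def __post_init__(self):
        ids = [e.label_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("label ids must be unique")
        if self.unlabeled_id not in ids:
            raise ValueError("unlabeled_id must be one of the entries")

    @property
    def ids(self) -> list[int]:
        return [e.label_id for e in self.entries]

    def __contains__(self, label_id: int) -> bool:
        return any(e.label_id == label_id for e in self.entries)

    def name_of(self, label_id: int) -> str:
        for e in self.entries:
            if e.label_id == label_id:
                return e.abbreviation
        raise KeyError(label_id)

    def to_dict(self) -> dict:
        return {
            "unlabeled_id": self.unlabeled_id,
            "entries": [
                [e.label_id, e.abbreviation, e.name] for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabelTable":
        return cls(
            [LabelEntry(int(i), a, n) for i, a, n in d["entries"]],
            unlabeled_id=int(d["unlabeled_id"]),
        )


_CORTICAL_24 = [
    (0, "UN", "Unlabeled"),
    (1, "ACiG", "Anterior cingulate gyrus"),
    (2, "pACiG", "Post anterior cingulate gyrus"),
    (3, "IFG", "Inferior frontal gyrus"),
    (4, "MFG", "Middle frontal gyrus"),
    (5, "OFC", "Orbitofrontal cortex"),
    (6, "PCG", "Pre-central gyrus"),
    (7, "SFG", "Superior frontal gyrus"),
    (8, "SG", "Straight gyrus"),
    (9, "FG", "Fusiform"),
    (10, "ITG", "Inferior temporal gyrus"),
    (11, "MTG", "Middle temporal gyrus"),
    (12, "PHG", "Parahippocampal gyrus"),
    (13, "STG", "Superior temporal gyrus"),
    (14, "TP", "Temporal pole"),
    (15, "PA", "Parietal"),
    (16, "PCiG", "Posterior cingulate gyrus"),
    (17, "PCuG", "Pre-cuneus gyrus"),
    (18, "PoCG", "Post-central gyrus"),
    (19, "CuG", "Cuneus"),
    (20, "ILOcG", "Inferior lateral occipital gyrus"),
    (21, "LG", "Lingual"),
    (22, "SLOcG", "Superior lateral occipital gyrus"),
    (23, "InsC", "Insula"),
    (24, "--", "Reserved cortical region"),
]

_FREESURFER_34 = [
    (0, "UN", "Unlabeled subcortical region"),
    (1, "BSTS", "Banks superior temporal sulcus"),
    (2, "cACC", "Caudal anterior cingulate cortex"),
    (3, "cMFG", "Caudal middle frontal gyrus"),
    (4, "CuG", "Cuneus cortex"),
    (5, "EC", "Entorhinal cortex"),
    (6, "FG", "Fusiform gyrus"),
    (7, "IPC", "Inferior parietal cortex"),
    (8, "ITG", "Inferior temporal gyrus"),
    (9, "iCC", "Isthmus-cingulate cortex"),
    (10, "LOC", "Lateral occipital cortex"),
    (11, "LOFC", "Lateral orbital frontal cortex"),
    (12, "LG", "Lingual gyrus"),
    (13, "MOFC", "Medial orbital frontal cortex"),
    (14, "MTG", "Middle temporal gyrus"),
    (15, "PHG", "Parahippocampal gyrus"),
    (16, "PCL", "Paracentral lobule"),
    (17, "POp", "Pars opercularis"),
    (18, "POr", "Pars orbitalis"),
    (19, "PTr", "Pars triangularis"),
    (20, "PCal", "Pericalcarine cortex"),
    (21, "PoCG", "Postcentral gyrus"),
    (22, "PCC", "Posterior-cingulate cortex"),
    (23, "PCG", "Precentral gyrus"),
    (24, "PCuG", "Precuneus cortex"),
    (25, "rACC", "Rostral anterior cingulate cortex"),
    (26, "rMFG", "Rostral middle frontal gyrus"),
    (27, "SFG", "Superior frontal gyrus"),
    (28, "SPC", "Superior parietal cortex"),
    (29, "STG", "Superior temporal gyrus"),
    (30, "SMG", "Supramarginal gyrus"),
    (31, "TP", "Temporal pole"),
    (32, "TTC", "Transverse temporal cortex"),
    (33, "InsC", "Insula"),
]


def cortical_24_table() -> LabelTable:
    """The 24-region (+ unlabeled) hemisphere parcellation scheme.

    Ids 1..23 are the named cortical regions; id 24 is kept so synthetic
    cohorts can exercise a full 24-region cortex plus the unlabeled cap.
    """
    return LabelTable([LabelEntry(*e) for e in _CORTICAL_24], unlabeled_id=0)


def freesurfer_table() -> LabelTable:
    """The 34-region FreeSurfer/Desikan scheme (33 cortical + unlabeled)."""
    return LabelTable([LabelEntry(*e) for e in _FREESURFER_34], unlabeled_id=0)
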