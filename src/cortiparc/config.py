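"""Pipeline configuration: every tunable of the published pipeline with
its shipped default, serializable to a single YAML file.

Defaults: surface post-processing decimates to 70,000 triangles and
smooths with 5 Laplacian iterations at relaxation 0.1; the registration
schedule is IC4/IS-distance, IC5/AP-distance, IC6/hull-depth,
IC7/mean-curvature with feature-smoothing lambda 0.5/0.5/0.5/1.0; the
rotational stage uses gradient tolerance 1e-6, max step 0.01 (halved per
level), min step 1e-9, relaxation 0.9, 30 iterations; the demons stage
uses epsilon = 1/sigma^2 with sigma set from the shortest grid edge,
deformation-smoothing strength 1.0, self-regulated mode on, minimum
metric change 0.05, 500 iterations, 40 smoothing iterations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .decimate import DEFAULT_TARGET_TRIANGLES
from .registration import DemonsParams, RotationParams, ScheduleLevel, default_schedule

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    target_triangles: int = DEFAULT_TARGET_TRIANGLES
    smoothing_iterations: int = 5
    smoothing_relaxation: float = 0.1
    schedule: list[ScheduleLevel] = field(default_factory=default_schedule)
    rotation: RotationParams = field(default_factory=RotationParams)
    demons: DemonsParams = field(default_factory=DemonsParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = [
            [l.index, l.ico_level, l.feature, l.normalization, l.lambda_feat]
            for l in self.schedule
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "schedule" in d:
            d["schedule"] = [ScheduleLevel(*row) for row in d["schedule"]]
        if "rotation" in d and isinstance(d["rotation"], dict):
            d["rotation"] = RotationParams(**d["rotation"])
        if "demons" in d and isinstance(d["demons"], dict):
            d["demons"] = DemonsParams(**d["demons"])
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
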