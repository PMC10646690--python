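"""Run configuration: design constants, seeds, and protocol parameters.

Defaults reproduce the study-scale protocol: 50 subjects, 6 runs x 16 blocks
x 8 trials (768 trials), 10,000 simulated voxels, voxel fractions
10/25/50/75/100%, 10 fit restarts, 25 comparison repetitions, 1,000 null
iterations over 200,000 voxels.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import InvalidParameterError
from .generative import StudyDesign


@dataclass
class RunConfig:
    # cohort design
    n_subjects: int = 50
    n_runs: int = 6
    blocks_per_run: int = 16
    trials_per_block: int = 8
    n_voxels: int = 10_000
    # analysis protocol
    fractions: tuple = (0.10, 0.25, 0.50, 0.75, 1.00)
    bounds: tuple = (0.0, 3.0)
    n_restarts: int = 10
    n_repetitions: int = 25
    # maximal-statistic nulls
    null_n_voxels: int = 200_000
    null_iterations: int = 1000
    # seeds
    seed: int = 0
    # output
    out_dir: str = "mapfactors_out"
    weights: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        for name in (
            "n_subjects",
            "n_runs",
            "blocks_per_run",
            "trials_per_block",
            "n_voxels",
            "n_restarts",
            "n_repetitions",
            "null_n_voxels",
            "null_iterations",
        ):
            value = getattr(self, name)
            if int(value) != value or value < 1:
                raise InvalidParameterError(f"{name} must be a positive integer, got {value!r}")
        if int(self.seed) != self.seed:
            raise InvalidParameterError(f"seed must be an integer, got {self.seed!r}")
        if not self.fractions or any(not 0 < f <= 1 for f in self.fractions):
            raise InvalidParameterError(f"fractions must lie in (0, 1], got {self.fractions!r}")
        lo, hi = self.bounds
        if not 0 <= lo < hi:
            raise InvalidParameterError(f"bounds must satisfy 0 <= lo < hi, got {self.bounds!r}")
        for key, value in self.weights.items():
            if not value >= 0:
                raise InvalidParameterError(f"weight {key} must be >= 0, got {value!r}")
        return self

    @property
    def design(self) -> StudyDesign:
        return StudyDesign(
            n_subjects=self.n_subjects,
            n_runs=self.n_runs,
            blocks_per_run=self.blocks_per_run,
            trials_per_block=self.trials_per_block,
            n_voxels=self.n_voxels,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        for key in ("fractions", "bounds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["fractions"] = list(self.fractions)
        data["bounds"] = list(self.bounds)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
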