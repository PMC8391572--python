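"""Run configuration: strict-schema YAML config shared by the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

_ALLOWED = {
    "constants_path", "seed", "aircraft_levels_dba", "road_levels_dba",
    "duration_s", "n_subjects", "rating_noise_sd", "tolerance_db",
    "out_dir", "verbose",
}


@dataclass
class RunConfig:
    """Every knob a CLI run needs; unknown keys are rejected."""

    constants_path: str | None = None
    seed: int = 0
    aircraft_levels_dba: list = field(default_factory=lambda: [63, 68, 73, 78, 83])
    road_levels_dba: list = field(default_factory=lambda: [55, 60, 65, 70, 75])
    duration_s: float = 20.0
    n_subjects: int = 50
    rating_noise_sd: float = 0.5
    tolerance_db: float = 0.05
    out_dir: str = "results"
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _ALLOWED
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def constants(self):
        from .constants import LoudnessModelConstants, default_constants

        if self.constants_path:
            return LoudnessModelConstants.from_yaml(self.constants_path)
        return default_constants()
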