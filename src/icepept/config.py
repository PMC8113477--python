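"""Run configuration: validated, fully serializable, hashable.

Unknown keys are rejected so a typo cannot silently fall back to a default;
every pipeline run writes the resolved config (with its hash) next to its
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, nested: dict | None = None):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    nested = nested or {}
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if f.name in nested and isinstance(v, dict):
                v = _from_dict(nested[f.name], v)
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class TrajectoryConfig:
    box: list = field(default_factory=lambda: [13.5, 13.5, 80.0])
    slab_thickness: float = 10.0
    growth_rate: float = 0.5
    frame_interval: float = 0.5
    n_frames: int = 160
    thermal_noise: float = 0.2
    t_bind: float | None = 60.0
    post_bind_rate_factor: float = 0.1


@dataclass
class ClassifyConfig:
    neighbor_cutoff: float = 3.5
    staggered_max: float = -0.8
    eclipsed_min: float = -0.35
    eclipsed_max: float = 0.25
    ice_like: list = field(default_factory=lambda: ["HEX", "CUBIC", "INT_ICE"])


@dataclass
class AnalysisConfig:
    r_shell: float = 5.4
    bin_width: float = 1.0
    front_smooth_window: int = 5
    torsion_smooth_window: int = 25
    k_ice: int = 4
    dwell: float = 5.0
    pdf_bin_width: float = 0.2


@dataclass
class RunConfig:
    """Top-level pipeline configuration (defaults = desk-scale profile)."""

    seed: int = 0
    n_trajectories: int = 3
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    activity_threshold: float = 0.8
    headline_concentration: float = 1.0
    lattice_params: list = field(default_factory=lambda: [4.50, 7.34])

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data, nested={
            "trajectory": TrajectoryConfig,
            "classify": ClassifyConfig,
            "analysis": AnalysisConfig,
        })

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
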