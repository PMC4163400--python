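"""Pipeline configuration.

All tunable parameters of every stage live here, with their defaults; a run
serializes its resolved configuration next to its outputs so results are
reproducible.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .errors import InvalidParameterError


@dataclass
class DiffusionConfig:
    iterations: int = 80  # sweeps of the explicit scheme
    sigma: float = 4.5  # edge parameter, intensity units
    # time step and 4-neighborhood are discretization conventions of this
    # implementation; only iterations and sigma are method-level parameters
    time_step: float = 0.20


@dataclass
class OuterConfig:
    image_type: str = "auto"  # A | B | auto
    smooth_sigma: float = 2.0  # Gaussian contour smoothing, px
    control_grid: int = 4  # coarsest B-spline lattice for the threshold field
    cv_trigger: float = 0.25  # boundary-intensity CV that triggers refinement in auto mode


@dataclass
class ClusterConfig:
    window_max_regions: int = 100  # cap of the local query window
    kernel_radius: float = 8.0  # seed-selection kernel radius, px


@dataclass
class BudsConfig:
    count_mode: str = "parents"  # parents | endpoints
    min_spur: int = 3  # prune skeleton branches shorter than this, px
    periphery_fraction: float = 0.25  # of the vertical extent


@dataclass
class PipelineConfig:
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    outer: OuterConfig = field(default_factory=OuterConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    buds: BudsConfig = field(default_factory=BudsConfig)
    pixel_size_um: float = 40.0  # stereo-microscope pixel resolution

    def __post_init__(self) -> None:
        if self.outer.image_type not in ("A", "B", "auto"):
            raise InvalidParameterError("outer.image_type must be A, B or auto")
        if self.buds.count_mode not in ("parents", "endpoints"):
            raise InvalidParameterError("buds.count_mode must be 'parents' or 'endpoints'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        section_types = {
            "diffusion": DiffusionConfig,
            "outer": OuterConfig,
            "cluster": ClusterConfig,
            "buds": BudsConfig,
        }
        valid = {f.name for f in fields(cls)}
        kwargs: dict = {}
        for key, value in d.items():
            if key not in valid:
                raise InvalidParameterError(f"unknown config key: {key!r}")
            if key in section_types and isinstance(value, dict):
                sub = section_types[key]
                sub_names = {sf.name for sf in fields(sub)}
                unknown = set(value) - sub_names
                if unknown:
                    raise InvalidParameterError(f"unknown config key(s) in {key}: {sorted(unknown)}")
                kwargs[key] = sub(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
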