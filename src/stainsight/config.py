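"""Pipeline configuration: defaults, YAML round-trip, validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .segmentation import DEFAULT_MIN_DEFICIT
from .synthetic import (
    OPTICS_PRESETS,
    STAIN_PROFILES,
    OpticsProfile,
    StainProfile,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on, fully serializable.

    The config (and its hash) is embedded in every report so a run can be
    reproduced from its output alone.
    """

    optics_preset: str = "microscope_4x"
    stain_deficits: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            name: p.deficit_rgb for name, p in STAIN_PROFILES.items()
        }
    )
    stage1_min_deficit: float = 10.0
    min_deficit: float = DEFAULT_MIN_DEFICIT
    min_object_area: float | None = None  # None -> 2 um disk at the optics scale
    cluster_cutoff_factor: float = 1.6
    ultra_low_max: float = 1000.0
    r2_threshold: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optics_preset not in OPTICS_PRESETS:
            raise ConfigurationError(
                f"unknown optics preset {self.optics_preset!r}; "
                f"choose from {sorted(OPTICS_PRESETS)}"
            )
        for name, d in self.stain_deficits.items():
            if len(d) != 3 or any(v < 0 for v in d):
                raise ConfigurationError(
                    f"stain_deficits[{name!r}] must be 3 non-negative values"
                )
        if self.min_deficit < 0 or self.stage1_min_deficit < 0:
            raise ConfigurationError("deficit thresholds must be >= 0")

    @property
    def optics(self) -> OpticsProfile:
        return OPTICS_PRESETS[self.optics_preset]

    def stain_profiles(self) -> dict[str, StainProfile]:
        out = {}
        for name, d in self.stain_deficits.items():
            base = STAIN_PROFILES.get(name)
            out[name] = StainProfile(
                name=name,
                deficit_rgb=tuple(float(v) for v in d),
                dominant_band=base.dominant_band
                if base and base.deficit_rgb == tuple(d)
                else None,
            )
        return out

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["stain_deficits"] = {k: list(v) for k, v in self.stain_deficits.items()}
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "stain_deficits" in kwargs:
            kwargs["stain_deficits"] = {
                k: tuple(float(x) for x in v)
                for k, v in kwargs["stain_deficits"].items()
            }
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"{path}: malformed YAML: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=int(seed))
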