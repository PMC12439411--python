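"""Pipeline configuration: every numeric constant of the method in one place.

Defaults are the method's published operating point (128^3 canonical cube,
10 mm / 30% alignment QC, N4 shrink 10 with a 60th-percentile mask, 80 mm
artefact radius, [0.8, 1.2] zoom band); a YAML file overrides any subset.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    side: int = 128
    offset_threshold_mm: float = 10.0
    overlap_threshold: float = 0.30
    shrink_factor: int = 10
    mask_percentile: float = 60.0
    center_radius_mm: float = 80.0
    zoom_band: tuple[float, float] = (0.8, 1.2)
    backend: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "zoom_band" in raw:
            raw["zoom_band"] = tuple(raw["zoom_band"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["zoom_band"] = list(self.zoom_band)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def require_backend(self) -> dict:
        if not self.backend or "kind" not in self.backend:
            raise ConfigurationError("config is missing the 'backend' section (key: kind)")
        return self.backend
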