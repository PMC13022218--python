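"""Run configuration: YAML round-trip, validation, content hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML.

    ``paths`` must name the wetlands GeoJSON, the scene directory, the
    samples CSV and the output directory; ``climate`` is optional.
    """

    paths: dict[str, str] = field(default_factory=dict)
    nutrients: list[str] = field(default_factory=lambda: ["N"])
    years: list[int] | None = None
    quarters: list[int] | None = None
    band_set: list[str] | None = None
    srvi_numerator: str = "vv"
    residual_source: str = "oob"
    model_scope: str = "per_quarter"
    rf_params: dict = field(default_factory=dict)
    train_fraction: float = 0.70
    seed: int = 0
    clip_negative: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        required = ("wetlands", "scenes", "samples", "output")
        missing = [k for k in required if k not in self.paths]
        if missing:
            raise ConfigError(f"config paths missing keys: {missing}")
        for key in ("wetlands", "scenes", "samples", "climate"):
            if key in self.paths and not Path(self.paths[key]).exists():
                raise ConfigError(f"path for '{key}' does not exist: "
                                  f"{self.paths[key]}")
        for n in self.nutrients:
            if n not in ("N", "P"):
                raise ConfigError(f"unknown nutrient {n!r}")
        if self.srvi_numerator not in ("vv", "vh"):
            raise ConfigError("srvi_numerator must be 'vv' or 'vh'")
        if self.residual_source not in ("oob", "insample"):
            raise ConfigError("residual_source must be 'oob' or 'insample'")
        if self.model_scope not in ("per_quarter", "pooled"):
            raise ConfigError("model_scope must be 'per_quarter' or 'pooled'")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.quarters is not None and not set(self.quarters) <= {1, 2, 3, 4}:
            raise ConfigError("quarters must be a subset of {1, 2, 3, 4}")
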