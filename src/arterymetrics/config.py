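"""Single pipeline configuration shared by all stages.

Every tunable of the measurement, conditioning, feature, simulation, and
evaluation stages lives here so a run is fully described by one TOML or
YAML file plus a seed. Unknown keys are rejected on load, and a stable
hash of the configuration is recorded in outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import yaml

from .features import PeakConfig
from .measurement import MeasurementConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # radial measurement
    beta_deg: float = 5.0
    n_angles: int = 360
    open_lumen_threshold: float = 2.0
    window_size: int = 15
    window_count_limit: int = 3
    # conditioning
    filter_window: int = 9
    # features
    theta_w: int = 10
    # evaluation
    ridge_alpha: float = 1.0
    # simulator
    canvas: int = 512
    radii: tuple[float, float, float] = (150.0, 105.0, 60.0)
    sigma: float = 30.0
    # reproducibility
    seed: int = 0
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        if self.filter_window % 2 != 1 or self.filter_window < 1:
            raise ValueError("filter_window must be an odd positive integer")
        if self.theta_w < 1:
            raise ValueError("theta_w must be >= 1")
        if self.ridge_alpha < 0:
            raise ValueError("ridge_alpha must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        # delegate the measurement-field checks
        self.measurement()

    # -- derived stage configs ---------------------------------------------
    def measurement(self) -> MeasurementConfig:
        return MeasurementConfig(
            beta_deg=self.beta_deg,
            n_angles=self.n_angles,
            open_lumen_threshold=self.open_lumen_threshold,
            window_size=self.window_size,
            window_count_limit=self.window_count_limit,
        )

    def peaks(self) -> PeakConfig:
        return PeakConfig(theta_w=self.theta_w)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["radii"] = list(d["radii"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "radii" in data:
            data = {**data, "radii": tuple(data["radii"])}
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            data = tomllib.loads(path.read_text())
        elif path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(path.read_text()) or {}
        else:
            raise ValueError(f"unsupported config format {path.suffix!r} (use .toml or .yaml)")
        return cls.from_dict(data)

    def hash(self) -> str:
        """Stable short hash of the configuration for output provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
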