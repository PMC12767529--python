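"""Pipeline configuration: defaults, YAML loading, validation."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """Every knob of the screen pipeline in one place.

    Flags given on the command line override values from the YAML file;
    the effective config is snapshotted into each run's manifest.
    """

    # paths
    design_path: str | None = None
    cells_path: str | None = None
    output_dir: str = "memascreen_out"
    # gating
    gating_method: str = "gmm"
    gating_scope: str = "array"
    # normalization
    ruv_k: int = 1
    loess_span: float = 0.5
    loess_min_spots: int = 20
    matrix_scope: str = "plate"
    signals: tuple[str, ...] = ("cell_count", "edu_prop", "dapi_median", "edu_median")
    # hit calling
    stratify: str = "ecm"
    test_unit: str = "spot"
    alpha: float = 0.05
    alternative: str = "two-sided"
    # reproducibility / logging
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.ruv_k < 0:
            raise ConfigurationError(f"ruv_k must be >= 0, got {self.ruv_k}")
        if not (0.0 < self.loess_span <= 1.0):
            raise ConfigurationError(
                f"loess_span must be in (0, 1], got {self.loess_span}"
            )
        if isinstance(self.signals, list):
            self.signals = tuple(self.signals)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["signals"] = list(out["signals"])
        return out
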