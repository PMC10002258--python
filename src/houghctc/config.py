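"""Pipeline configuration with the assay's published defaults.

Defaults: 0.75 pixel/um resolution, a 10-400 px component-area window,
circularity cut 0.6, cell diameters 5-25 um (Hough radii 2-10 px), and a
7 mL blood draw for per-mL densities.  Every value is overridable from
YAML/JSON, and the effective configuration is serialized next to each
run's outputs so results are reproducible from the artifacts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    resolution: float = 0.75            # pixel/um; required, never inferred
    min_area_px: int = 10
    max_area_px: int = 400
    min_circularity: float = 0.6
    cell_diameter_um: tuple[float, float] = (5.0, 25.0)
    sensitivity: float = 0.65           # circle acceptance = support >= 1 - sensitivity
    high_sensitivity: float = 0.75      # used where overlapping clusters dominate
    min_center_distance: float = 2.0    # px, = default r_min
    upsample: int = 2
    blood_volume_ml: float = 7.0
    component_red_veto: bool = False    # veto whole components touching CD45, not pixels
    manual_thresholds: dict = dc_field(default_factory=dict)  # {"blue": int, ...}
    channel_map: dict | None = None
    exclusion_file: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution is None or not self.resolution > 0:
            raise ConfigurationError("resolution (pixel/um) must be positive")
        if not 0 < self.min_area_px <= self.max_area_px:
            raise ConfigurationError("need 0 < min_area_px <= max_area_px")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ConfigurationError("sensitivity must lie in [0, 1]")
        if self.blood_volume_ml <= 0:
            raise ConfigurationError("blood_volume_ml must be positive")
        self.cell_diameter_um = tuple(self.cell_diameter_um)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Path | str) -> None:
        data = asdict(self)
        data["cell_diameter_um"] = list(self.cell_diameter_um)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
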