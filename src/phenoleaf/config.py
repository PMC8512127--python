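"""Pipeline configuration.

A single dataclass holds every tunable knob of the detection, sequence,
counting, and evaluation stages, with defaults matching the documented
design choices of each module.  Configs round-trip through YAML so an
effective-config file saved beside an output directory reruns to
identical results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is invalid."""


@dataclass
class PipelineConfig:
    """All pipeline parameters with their defaults.

    Attributes
    ----------
    method : str
        Detection method, one of M1..M6 (single or combined Otsu runs) or
        M4_SQ / M5_SQ (image-sequence variants of M4 / M5).
    channel_mode : str
        Grayscale conversion: ``luma`` (0.299 R + 0.587 G + 0.114 B) or
        ``lab_a`` (CIELAB a-channel rescaled to [0, 255]).
    resize : bool
        Halve image dimensions before processing (1280x1024 -> 640x512).
    interpolation : str
        Resize interpolation, ``bilinear`` or ``nearest``.
    border_policy : str
        Convolution border handling for the sharpening filter.
    fg_rule : str
        Which Otsu class becomes foreground: ``top_class`` (brightest) or
        ``brightest_valid_class`` (brightest class whose components pass
        the area filter).
    merge_tol_px : int
        Pixel tolerance of the box-merge rules, at the 640x512 working
        resolution.
    area_min_frac, area_max_frac : float
        Component area bounds as fractions of the frame pixel count.
    hu_tol : float
        Maximum log-Hu-moment distance to the reference shape.
    connectivity : int
        Connected-component connectivity (4 or 8).
    day_start, day_end : str
        Daytime window "HH:MM"; start inclusive, end exclusive.
    marker_min_distance : int
        Minimum separation of distance-map maxima used as watershed seeds.
    marker_rel_height : float
        Maxima must reach this fraction of the global distance maximum.
    flood_connectivity : int
        Watershed flooding connectivity (4 keeps ridge lines thin).
    leaf_area_min : int
        Watershed regions smaller than this are merged into a neighbour
        instead of being counted as leaves.
    count_n_classes : int
        Otsu class count used to re-threshold a plant crop when counting
        without a precomputed mask.
    iou_min : float
        Intersection-over-union threshold for detection/ground-truth
        matching.
    seed : int
        Seed for any stochastic step (synthetic generation).
    """

    method: str = "M4"
    channel_mode: str = "luma"
    resize: bool = True
    interpolation: str = "bilinear"
    border_policy: str = "replicate"
    fg_rule: str = "top_class"
    merge_tol_px: int = 30
    area_min_frac: float = 0.001
    area_max_frac: float = 0.25
    hu_tol: float = 1.5
    connectivity: int = 8
    day_start: str = "05:00"
    day_end: str = "18:00"
    marker_min_distance: int = 7
    marker_rel_height: float = 0.5
    flood_connectivity: int = 4
    leaf_area_min: int = 25
    count_n_classes: int = 3
    iou_min: float = 0.5
    seed: int = 0

    _VALID = {
        "method": {"M1", "M2", "M3", "M4", "M5", "M6", "M4_SQ", "M5_SQ"},
        "channel_mode": {"luma", "lab_a"},
        "interpolation": {"bilinear", "nearest"},
        "border_policy": {"replicate", "reflect", "constant"},
        "fg_rule": {"top_class", "brightest_valid_class"},
        "connectivity": {4, 8},
        "flood_connectivity": {4, 8},
    }

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key, allowed in self._VALID.items():
            if getattr(self, key) not in allowed:
                raise ConfigError(
                    f"{key}={getattr(self, key)!r} not in {sorted(map(str, allowed))}"
                )
        if not 0 < self.area_min_frac < self.area_max_frac <= 1:
            raise ConfigError("need 0 < area_min_frac < area_max_frac <= 1")
        if not 0 < self.marker_rel_height <= 1:
            raise ConfigError("marker_rel_height must be in (0, 1]")
        if self.marker_min_distance < 1:
            raise ConfigError("marker_min_distance must be >= 1")
        if not 0 < self.iou_min <= 1:
            raise ConfigError("iou_min must be in (0, 1]")
        for key in ("day_start", "day_end"):
            value = getattr(self, key)
            parts = value.split(":")
            if len(parts) != 2 or not all(p.isdigit() for p in parts):
                raise ConfigError(f"{key}={value!r} is not HH:MM")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
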