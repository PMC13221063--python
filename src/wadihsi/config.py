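"""Pipeline configuration: one validated object holding every tunable knob."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis.

    Unknown keys in a config file are rejected loudly rather than ignored,
    so typos cannot silently fall back to defaults.
    """

    seed: int = 0
    n_sites: int = 12
    parameters: list[str] = field(default_factory=list)  # empty = all available
    quantile_interpolation: str = "linear"
    threshold_preset: str | None = None  # None = data-driven quantiles
    n_boot: int = 1000
    boyce_windows: int = 10
    boyce_window_width: float | None = None
    mess_strong_threshold: float = -10.0
    gap_percentile: float = 90.0
    gap_targets: dict[str, float] = field(
        default_factory=lambda: {"national_2040": 7.5, "cbd_30x30": 30.0}
    )
    grid_shape: tuple[int, int] = (60, 60)
    pa_fraction: float = 0.056
    cell_area_km2: float = 1.0
    include_texture: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.boyce_windows < 2:
            raise ValueError("boyce_windows must be >= 2")
        if not 0 < self.gap_percentile < 100:
            raise ValueError("gap_percentile must be in (0, 100)")
        if not 0 < self.pa_fraction < 1:
            raise ValueError("pa_fraction must be in (0, 1)")
        if self.cell_area_km2 <= 0:
            raise ValueError("cell_area_km2 must be positive")
        if any(t <= 0 for t in self.gap_targets.values()):
            raise ValueError("gap targets must be positive percentages")
        self.grid_shape = tuple(self.grid_shape)
        if len(self.grid_shape) != 2 or any(d < 1 for d in self.grid_shape):
            raise ValueError("grid_shape must be two positive integers")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - valid)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d
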