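"""Analysis configuration: every tunable of the capture/analysis pipeline.

A single :class:`CasaSettings` object travels through segmentation, linking,
kinematics, quantitation and QC, so one file (TOML) is the source of truth
for a run.  Defaults correspond to a 60 Hz, 0.75 s darkfield capture of a
20 µm deep counting chamber.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from typing import Any, Mapping

__all__ = ["CasaSettings", "load_settings", "save_settings", "SettingsError"]


class SettingsError(ValueError):
    """Raised for an invalid configuration value, naming the field."""


_STATIC_TAIL_FILTER_RATIONALE = (
    "static_tail_filter must remain False: with tail detection enabled, "
    "cells whose tails are not resolved are dropped entirely, which "
    "under-estimates concentration and over-estimates motility. Heads only."
)


@dataclass
class CasaSettings:
    """Full pipeline configuration.

    Velocity thresholds are in µm/s, areas in µm², lengths in µm.
    ``working_range`` / ``ideal_range`` are concentration bands in cells/mL.
    """

    # capture
    frame_rate_hz: float = 60.0
    capture_duration_s: float = 0.75
    microns_per_pixel: float = 1.0

    # detection
    min_head_area_um2: float = 5.0
    max_head_area_um2: float = 150.0
    fixed_threshold: float | None = None  # None -> Otsu per frame
    mask_percentile: float = 99.5
    static_tail_filter: bool = False  # immutable design constraint

    # tracking
    cell_travel_max_um: float = 10.0

    # kinematics / classification
    static_width_multiplier: float = 0.8
    slow_bound_um_s: float = 20.0
    progressive_bound_um_s: float = 80.0
    classification_velocity: str = "vap"  # vap | vcl | vsl
    smoothing_frames: int = 5
    min_track_frames: int = 30
    expected_max_speed_um_s: float = 300.0

    # quantitation
    chamber_depth_um: float = 20.0
    dilution_factor: float = 1.0

    # QC
    min_fields: int = 5
    min_cells: int = 200
    working_range: tuple[float, float] = (8.0e6, 5.0e7)
    ideal_range: tuple[float, float] = (1.0e7, 3.0e7)
    drift_threshold_um_s: float = 10.0
    stale_well_max_s: float = 120.0

    seed: int | None = None

    def __post_init__(self) -> None:
        self.working_range = tuple(self.working_range)  # type: ignore[assignment]
        self.ideal_range = tuple(self.ideal_range)  # type: ignore[assignment]
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.static_tail_filter:
            raise SettingsError(_STATIC_TAIL_FILTER_RATIONALE)
        positive = [
            "frame_rate_hz",
            "capture_duration_s",
            "microns_per_pixel",
            "min_head_area_um2",
            "max_head_area_um2",
            "cell_travel_max_um",
            "static_width_multiplier",
            "slow_bound_um_s",
            "progressive_bound_um_s",
            "chamber_depth_um",
            "dilution_factor",
            "drift_threshold_um_s",
            "stale_well_max_s",
            "expected_max_speed_um_s",
        ]
        for name in positive:
            value = getattr(self, name)
            if not value > 0:
                raise SettingsError(f"{name} must be positive, got {value!r}")
        if self.min_head_area_um2 >= self.max_head_area_um2:
            raise SettingsError(
                "min_head_area_um2 must be below max_head_area_um2 "
                f"({self.min_head_area_um2} >= {self.max_head_area_um2})"
            )
        if not self.slow_bound_um_s < self.progressive_bound_um_s:
            raise SettingsError(
                "slow_bound_um_s must be below progressive_bound_um_s "
                f"({self.slow_bound_um_s} >= {self.progressive_bound_um_s})"
            )
        if self.classification_velocity not in ("vap", "vcl", "vsl"):
            raise SettingsError(
                "classification_velocity must be one of 'vap', 'vcl', 'vsl', "
                f"got {self.classification_velocity!r}"
            )
        if self.smoothing_frames < 1 or self.smoothing_frames % 2 == 0:
            raise SettingsError(
                f"smoothing_frames must be a positive odd integer, got {self.smoothing_frames}"
            )
        if self.min_track_frames < 2:
            raise SettingsError(
                f"min_track_frames must be >= 2, got {self.min_track_frames}"
            )
        if self.min_fields < 1 or self.min_cells < 1:
            raise SettingsError("min_fields and min_cells must be >= 1")
        for name in ("working_range", "ideal_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise SettingsError(f"{name} must satisfy 0 < low < high, got ({lo}, {hi})")
        if not (0 <= self.mask_percentile <= 100):
            raise SettingsError(
                f"mask_percentile must be in [0, 100], got {self.mask_percentile}"
            )

    # -- derived quantities ---------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(round(self.capture_duration_s * self.frame_rate_hz))

    @property
    def max_trackable_vcl_um_s(self) -> float:
        """Fastest curvilinear velocity that linking can follow unbroken."""
        return self.cell_travel_max_um * self.frame_rate_hz

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["working_range"] = list(self.working_range)
        d["ideal_range"] = list(self.ideal_range)
        return d

    def replace(self, **overrides: Any) -> "CasaSettings":
        return dataclasses.replace(self, **overrides)


_FIELD_TYPES = {f.name: f for f in dataclasses.fields(CasaSettings)}


def _coerce(name: str, value: Any) -> Any:
    if name not in _FIELD_TYPES:
        raise SettingsError(f"unknown setting {name!r}")
    if name in ("working_range", "ideal_range"):
        lo, hi = value
        return (float(lo), float(hi))
    if name == "seed":
        return None if value in (None, "", "none") else int(value)
    if name == "fixed_threshold":
        return None if value in (None, "", "none") else float(value)
    if name == "static_tail_filter":
        if isinstance(value, str):
            return value.strip().lower() in ("true", "1", "yes")
        return bool(value)
    if name in ("smoothing_frames", "min_track_frames", "min_fields", "min_cells"):
        return int(value)
    if name == "classification_velocity":
        return str(value)
    return float(value)


def load_settings(path: str | None = None, overrides: Mapping[str, Any] | None = None) -> CasaSettings:
    """Build settings from defaults, then a TOML file, then explicit overrides.

    An empty (or absent) file yields pure defaults.  Unknown keys and invalid
    values raise :class:`SettingsError` with the offending field name.
    """
    values: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        for key, value in raw.items():
            values[key] = _coerce(key, value)
    if overrides:
        for key, value in overrides.items():
            values[key] = _coerce(key, value)
    return CasaSettings(**values)


def _toml_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"cannot serialise {value!r}")


def save_settings(settings: CasaSettings, path: str) -> None:
    """Write settings as TOML; ``load_settings`` of the result round-trips."""
    lines = []
    for key, value in settings.to_dict().items():
        if value is None:
            continue  # tomllib has no null; absent key -> default None
        lines.append(f"{key} = {_toml_value(value)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
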