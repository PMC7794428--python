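"""Capture-quality checks as machine-checkable flags.

Each check is a pure function of its inputs; flags are plain strings so they
serialise directly into sample reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "QcReport",
    "DriftReport",
    "StalenessReport",
    "check_capture",
    "check_working_range",
    "detect_uniform_flow",
    "check_staleness",
]

FLAG_INSUFFICIENT_FIELDS = "insufficient_fields"
FLAG_INSUFFICIENT_CELLS = "insufficient_cells"
FLAG_BELOW_WORKING_RANGE = "below_working_range"
FLAG_ABOVE_WORKING_RANGE = "above_working_range"
FLAG_OUTSIDE_IDEAL_RANGE = "outside_ideal_range"
FLAG_UNIFORM_FLOW = "uniform_flow_detected"
FLAG_STALE_WELL = "stale_well"
FLAG_SPLIT_RISK = "split_risk"


@dataclass
class QcReport:
    flags: frozenset[str] = frozenset()
    diagnostics: dict[str, Any] = field(default_factory=dict)


def check_capture(
    n_fields: int, n_cells: int, min_fields: int = 5, min_cells: int = 200
) -> set[str]:
    """Flag captures with too few fields or too few measured cells."""
    if n_fields < 0 or n_cells < 0:
        raise ValueError("counts cannot be negative")
    flags: set[str] = set()
    if n_fields < min_fields:
        flags.add(FLAG_INSUFFICIENT_FIELDS)
    if n_cells < min_cells:
        flags.add(FLAG_INSUFFICIENT_CELLS)
    return flags


def check_working_range(
    concentration_cells_ml: float,
    working_range: tuple[float, float] = (8.0e6, 5.0e7),
    ideal_range: tuple[float, float] = (1.0e7, 3.0e7),
) -> set[str]:
    """Flag concentrations outside the analysable / ideal bands.

    Outside the working range the hard below/above flags fire; within the
    working range but outside the ideal band only the soft
    ``outside_ideal_range`` flag fires.
    """
    if concentration_cells_ml < 0:
        raise ValueError("concentration cannot be negative")
    c = concentration_cells_ml
    flags: set[str] = set()
    if c < working_range[0]:
        flags.add(FLAG_BELOW_WORKING_RANGE)
    elif c > working_range[1]:
        flags.add(FLAG_ABOVE_WORKING_RANGE)
    elif not (ideal_range[0] <= c <= ideal_range[1]):
        flags.add(FLAG_OUTSIDE_IDEAL_RANGE)
    return flags


@dataclass(frozen=True)
class DriftReport:
    drift_um_s: tuple[float, float]
    magnitude_um_s: float
    flagged: bool
    n_tracks: int
    sufficient_tracks: bool


def _positions_of(track: Any) -> np.ndarray:
    if hasattr(track, "positions"):
        return np.asarray(track.positions, dtype=float)
    return np.asarray(track, dtype=float)


def detect_uniform_flow(
    tracks: Sequence[Any],
    frame_rate_hz: float,
    drift_threshold_um_s: float = 10.0,
    min_tracks: int = 5,
) -> DriftReport:
    """Estimate bulk drift (µm/s) and flag uniform flow in the chamber.

    Drift is the component-wise *median* of all per-step displacement vectors
    across tracks, scaled by the frame rate — the median is robust to the
    motile subpopulation's own swimming.  With fewer than ``min_tracks``
    tracks the estimate is reported as a diagnostic but never flagged.
    Accepts :class:`~coralcasa.tracking.Track` objects or raw (n, 2) arrays.
    """
    steps: list[np.ndarray] = []
    n_tracks = 0
    for track in tracks:
        positions = _positions_of(track)
        if len(positions) >= 2:
            steps.append(np.diff(positions, axis=0))
            n_tracks += 1
    if not steps:
        return DriftReport((0.0, 0.0), 0.0, False, 0, False)
    all_steps = np.concatenate(steps, axis=0)
    drift = np.median(all_steps, axis=0) * frame_rate_hz
    magnitude = float(np.hypot(*drift))
    sufficient = n_tracks >= min_tracks
    flagged = sufficient and magnitude > drift_threshold_um_s
    return DriftReport(
        drift_um_s=(float(drift[0]), float(drift[1])),
        magnitude_um_s=magnitude,
        flagged=flagged,
        n_tracks=n_tracks,
        sufficient_tracks=sufficient,
    )


@dataclass(frozen=True)
class StalenessReport:
    elapsed_s: float | None
    flagged: bool
    status: str  # "ok" | "stale" | "unknown"


def check_staleness(
    load_time: float | None,
    capture_time: float | None,
    max_delay_s: float = 120.0,
) -> StalenessReport:
    """Flag wells analysed too long after loading.

    Sperm migrate toward well edges over time, so a delayed capture
    under-estimates concentration.  Missing timestamps yield status
    ``"unknown"`` and no flag.
    """
    if load_time is None or capture_time is None:
        return StalenessReport(elapsed_s=None, flagged=False, status="unknown")
    if capture_time < load_time:
        raise ValueError("capture_time precedes load_time")
    elapsed = float(capture_time - load_time)
    stale = elapsed > max_delay_s
    return StalenessReport(
        elapsed_s=elapsed, flagged=stale, status="stale" if stale else "ok"
    )
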