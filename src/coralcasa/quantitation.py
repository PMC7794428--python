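"""Concentration and motility quantitation, across three instruments.

Chamber-based (video) concentration derives from the mean number of
detections per frame and the imaged chamber volume.  Haemocytometer and
flow-cytometer formulas are implemented exactly as used in practice so the
three instruments can be cross-checked on the same sample.

Note on the haemocytometer equation: the literal published form multiplies
the raw cell count by the number of grid cells counted (``CC x N x CD x D``).
Averaging over grid cells (``CC / N``) is the more common convention; both
are provided, the literal product being the default.  Neither is silently
"corrected" into the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "FieldResult",
    "SampleResult",
    "HaemocytometerCount",
    "FlowAcquisition",
    "DilutionPlan",
    "field_concentration",
    "aggregate_sample",
    "haemocytometer_concentration",
    "flow_concentration",
    "dilution_plan",
]

_UM3_PER_ML = 1.0e12  # 1 mL = 1 cm^3 = 1e12 µm^3


@dataclass
class FieldResult:
    """Aggregate of one captured field: class counts and concentration."""

    field_id: str
    class_counts: dict[str, int]
    field_area_um2: float
    chamber_depth_um: float
    concentration_cells_ml: float
    dilution: float = 1.0
    mean_detections_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if self.dilution < 1.0:
            raise ValueError(f"dilution factor must be >= 1, got {self.dilution}")
        if self.concentration_cells_ml < 0:
            raise ValueError("concentration cannot be negative")

    @property
    def total_cells(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class SampleResult:
    """Per-sample summary: motility percentages, concentrations, QC flags.

    Percentages are ``None`` (reported as missing, never 0) when no cells
    were classified.
    """

    sample_id: str
    n_fields: int
    n_cells: int
    total_motility_pct: float | None
    progressive_motility_pct: float | None
    total_concentration_cells_ml: float
    motile_concentration_cells_ml: float | None
    class_counts: dict[str, int] = field(default_factory=dict)
    treatment: str | None = None
    qc_flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class HaemocytometerCount:
    """One haemocytometer reading.

    ``cell_count`` (CC) cells seen over ``n_grid_cells`` (N) grid cells
    (each a 4x4 block of smallest squares; count at least 3),
    ``chamber_depth_factor`` (CD) and ``dilution`` (D).
    """

    cell_count: float
    n_grid_cells: float
    chamber_depth_factor: float
    dilution: float

    def __post_init__(self) -> None:
        for name in ("cell_count", "n_grid_cells", "chamber_depth_factor", "dilution"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class FlowAcquisition:
    """A gated flow-cytometer acquisition (default 10 µL collected)."""

    gated_events: float
    dilution: float = 1.0
    acquisition_volume_ul: float = 10.0

    def __post_init__(self) -> None:
        if self.gated_events < 0:
            raise ValueError("gated_events cannot be negative")
        if not self.acquisition_volume_ul > 0:
            raise ValueError("acquisition_volume_ul must be positive")
        if not self.dilution > 0:
            raise ValueError("dilution must be positive")


def field_concentration(
    n_cells_mean_per_frame: float,
    field_area_um2: float,
    chamber_depth_um: float,
    dilution: float = 1.0,
) -> float:
    """Cells/mL from the mean per-frame count and the imaged chamber volume.

    The imaged volume is ``field_area x chamber_depth`` in µm³, i.e.
    ``x 1e-12`` mL; the result is scaled back up by the dilution factor.
    """
    if not field_area_um2 > 0 or not chamber_depth_um > 0:
        raise ValueError("field area and chamber depth must be positive")
    if n_cells_mean_per_frame < 0:
        raise ValueError("cell count cannot be negative")
    volume_ml = field_area_um2 * chamber_depth_um / _UM3_PER_ML
    return n_cells_mean_per_frame / volume_ml * dilution


def aggregate_sample(
    fields: list[FieldResult],
    sample_id: str = "sample",
    treatment: str | None = None,
    min_fields: int = 5,
    min_cells: int = 200,
) -> SampleResult:
    """Pool per-field results into a sample summary with capture QC flags.

    Total motility excludes static cells; motile concentration is the total
    concentration scaled by the total-motility fraction.  Samples with fewer
    than ``min_fields`` fields or ``min_cells`` classified cells are flagged
    rather than rejected.
    """
    if not fields:
        raise ValueError("aggregate_sample needs at least one field")
    counts: dict[str, int] = {"static": 0, "slow": 0, "motile": 0, "progressive": 0}
    for fr in fields:
        for cls, n in fr.class_counts.items():
            counts[cls] = counts.get(cls, 0) + n
    n_cells = sum(counts.values())
    total_concentration = sum(f.concentration_cells_ml for f in fields) / len(fields)

    flags: list[str] = []
    if len(fields) < min_fields:
        flags.append("insufficient_fields")
    if n_cells < min_cells:
        flags.append("insufficient_cells")

    if n_cells == 0:
        flags.append("no_cells")
        total_motility = progressive_motility = motile_concentration = None
    else:
        moving = counts["slow"] + counts["motile"] + counts["progressive"]
        total_motility = 100.0 * moving / n_cells
        progressive_motility = 100.0 * counts["progressive"] / n_cells
        motile_concentration = total_concentration * total_motility / 100.0

    return SampleResult(
        sample_id=sample_id,
        n_fields=len(fields),
        n_cells=n_cells,
        total_motility_pct=total_motility,
        progressive_motility_pct=progressive_motility,
        total_concentration_cells_ml=total_concentration,
        motile_concentration_cells_ml=motile_concentration,
        class_counts=counts,
        treatment=treatment,
        qc_flags=tuple(flags),
    )


def haemocytometer_concentration(
    count: HaemocytometerCount, mode: str = "literal"
) -> float:
    """Haemocytometer concentration in cells/mL.

    ``mode="literal"`` applies the published product ``CC x N x CD x D``
    verbatim; ``mode="mean"`` uses the per-grid-cell mean ``(CC / N) x CD x D``.
    """
    cc, n = count.cell_count, count.n_grid_cells
    cd, d = count.chamber_depth_factor, count.dilution
    if mode == "literal":
        return cc * n * cd * d
    if mode == "mean":
        return cc / n * cd * d
    raise ValueError(f"mode must be 'literal' or 'mean', got {mode!r}")


def flow_concentration(acquisition: FlowAcquisition) -> float:
    """Flow-cytometer concentration: events x dilution x (1000 µL / volume).

    At the default 10 µL acquisition the per-mL factor is exactly 100.
    """
    per_ml_factor = 1000.0 / acquisition.acquisition_volume_ul
    return acquisition.gated_events * acquisition.dilution * per_ml_factor


@dataclass(frozen=True)
class DilutionPlan:
    status: str  # "ok" | "in_range" | "below_range"
    factor: float | None
    resulting_concentration_cells_ml: float | None


def dilution_plan(
    current_concentration_cells_ml: float,
    target_range: tuple[float, float],
) -> DilutionPlan:
    """Smallest practical dilution factor bringing a sample into range.

    Samples already in range need no dilution (factor 1); samples below the
    range cannot be concentrated and are reported as such.  Over-concentrated
    samples get the smallest decade factor (10, 100, ...) that lands inside
    the range — matching bench practice of serial decimal dilutions — falling
    back to the smallest integer, then exact, factor for narrow ranges.
    """
    low, high = target_range
    if not (0 < low < high):
        raise ValueError(f"target range must satisfy 0 < low < high, got {target_range}")
    conc = current_concentration_cells_ml
    if not conc > 0:
        raise ValueError("current concentration must be positive")
    if conc < low:
        return DilutionPlan(status="below_range", factor=None,
                            resulting_concentration_cells_ml=None)
    if conc <= high:
        return DilutionPlan(status="in_range", factor=1.0,
                            resulting_concentration_cells_ml=conc)
    decade = 10.0 ** math.ceil(math.log10(conc / high))
    if conc / decade >= low:
        factor = decade
    else:
        integer = float(math.ceil(conc / high))
        factor = integer if conc / integer >= low else conc / high
    return DilutionPlan(status="ok", factor=factor,
                        resulting_concentration_cells_ml=conc / factor)
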