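"""Ground-truthed synthetic sperm captures and fertilisation datasets.

Every downstream stage — segmentation, linking, kinematics, classification,
quantitation, QC — is testable against this module's known truth, with no
real microscopy data.

A capture is simulated in two stages:

1. :func:`simulate_tracks` places a Poisson number of cells in the field
   (mean = concentration x field area x chamber depth) and moves each by its
   class's motion model for the capture duration.  Static cells jitter inside
   a radius safely below the static-classification bound
   (0.8 x head diameter); slow and motile cells follow persistent random
   walks at a sampled speed; progressive cells swim near-straight.  A uniform
   drift can be superimposed on everyone (the "uniform flow" loading
   artefact), and cells that leave the field keep their partial track.
2. :func:`render_frames` draws each cell as a 2-D Gaussian spot whose area at
   the half-maximum detection level equals its head area, optionally adds
   static saturated "bloom" discs (dust/salt artefacts) and Gaussian noise.

Per-class speed ranges are deliberately configurable: they differ by species
and by month, so the defaults are placeholders chosen to sit well inside the
classification bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detection import FrameStack, head_diameter
from .fertilisation import FertilisationRecord

__all__ = [
    "MotilityMixture",
    "FieldGeometry",
    "TruthCell",
    "GroundTruth",
    "OpticsSpec",
    "FertParams",
    "CalibrationError",
    "simulate_tracks",
    "render_frames",
    "synth_fert_dataset",
    "truth_detections",
]

CLASS_NAMES = ("static", "slow", "motile", "progressive")

# Safety margin on the static radius: truth static cells stay well inside the
# classification bound so sub-pixel detection noise cannot flip their class.
_STATIC_RADIUS_FRACTION = 0.5


class CalibrationError(ValueError):
    """Pixel calibration too coarse to render a head as a resolvable spot."""


@dataclass(frozen=True)
class FieldGeometry:
    """Imaged field (µm) and chamber depth (µm)."""

    width_um: float = 640.0
    height_um: float = 480.0
    depth_um: float = 20.0

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0 and self.depth_um > 0):
            raise ValueError(f"field geometry must be positive: {self}")

    @property
    def volume_ml(self) -> float:
        return self.width_um * self.height_um * self.depth_um * 1e-12


@dataclass
class MotilityMixture:
    """Composition and motion parameters of a simulated sperm population.

    Class fractions must sum to 1; each class's speed range must sit inside
    its classification bin (slow below 20 µm/s, motile within [20, 80],
    progressive above 80) so truth labels match intended classifier output.
    """

    fraction_static: float = 0.25
    fraction_slow: float = 0.25
    fraction_motile: float = 0.25
    fraction_progressive: float = 0.25
    concentration_cells_ml: float = 2.0e7
    speed_range_um_s: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "slow": (8.0, 15.0),
            "motile": (30.0, 70.0),
            "progressive": (90.0, 150.0),
        }
    )
    directional_persistence: dict[str, float] = field(
        default_factory=lambda: {"slow": 0.95, "motile": 0.9, "progressive": 0.98}
    )
    static_jitter_sd_um: float = 0.1
    head_area_range_um2: tuple[float, float] = (8.0, 20.0)
    drift_velocity_um_s: tuple[float, float] = (0.0, 0.0)
    bloom_count: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "static": self.fraction_static,
            "slow": self.fraction_slow,
            "motile": self.fraction_motile,
            "progressive": self.fraction_progressive,
        }

    def validate(
        self, slow_bound_um_s: float = 20.0, progressive_bound_um_s: float = 80.0
    ) -> None:
        fracs = self.fractions
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"fraction_{name} must lie in [0, 1], got {value}")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {sum(fracs.values())!r}")
        if not self.concentration_cells_ml > 0:
            raise ValueError("concentration must be positive")
        if self.static_jitter_sd_um < 0:
            raise ValueError("static_jitter_sd_um cannot be negative")
        lo, hi = self.head_area_range_um2
        if not (0 < lo <= hi):
            raise ValueError(f"head_area_range_um2 invalid: {self.head_area_range_um2}")
        bins = {
            "slow": (0.0, slow_bound_um_s, "[0, slow_bound)"),
            "motile": (slow_bound_um_s, progressive_bound_um_s, "[slow, progressive]"),
            "progressive": (progressive_bound_um_s, math.inf, "(progressive, inf)"),
        }
        for cls, (lo_s, hi_s) in self.speed_range_um_s.items():
            if cls not in bins:
                raise ValueError(f"unknown speed class {cls!r}")
            if not (0 <= lo_s <= hi_s):
                raise ValueError(f"speed range for {cls} invalid: ({lo_s}, {hi_s})")
            b_lo, b_hi, label = bins[cls]
            inside = (
                lo_s > b_lo if cls == "progressive" else lo_s >= b_lo
            ) and (hi_s < b_hi if cls == "slow" else hi_s <= b_hi)
            if not inside:
                raise ValueError(
                    f"{cls} speed range ({lo_s}, {hi_s}) must lie inside its "
                    f"classification bin {label}"
                )
        for cls, p in self.directional_persistence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"persistence for {cls} must be in [0, 1], got {p}")


@dataclass
class TruthCell:
    """One simulated cell: label, head size and per-frame positions (µm)."""

    cell_id: int
    motility_class: str
    head_area_um2: float
    frames: np.ndarray  # consecutive ints starting at first in-field frame
    positions: np.ndarray  # (n, 2) of (x, y) µm

    @property
    def head_diameter_um(self) -> float:
        return head_diameter(self.head_area_um2)

    @property
    def max_displacement_um(self) -> float:
        offsets = self.positions - self.positions[0]
        return float(np.hypot(offsets[:, 0], offsets[:, 1]).max())


@dataclass
class GroundTruth:
    """Complete simulated capture: all cells plus capture geometry."""

    cells: list[TruthCell]
    geometry: FieldGeometry
    frame_rate_hz: float
    n_frames: int

    def class_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in CLASS_NAMES}
        for cell in self.cells:
            counts[cell.motility_class] += 1
        return counts

    def cells_in_frame(self, frame: int) -> list[tuple[TruthCell, np.ndarray]]:
        out = []
        for cell in self.cells:
            offset = frame - int(cell.frames[0])
            if 0 <= offset < len(cell.frames):
                out.append((cell, cell.positions[offset]))
        return out


def _simulate_static(
    rng: np.random.Generator, start: np.ndarray, n_frames: int,
    jitter_sd: float, radius_limit: float,
) -> np.ndarray:
    positions = np.empty((n_frames, 2))
    offset = np.zeros(2)
    positions[0] = start
    for i in range(1, n_frames):
        offset = offset + rng.normal(0.0, jitter_sd, size=2)
        norm = math.hypot(*offset)
        if norm > radius_limit:  # clip back inside the allowed radius
            offset *= radius_limit / norm
        positions[i] = start + offset
    return positions


def _simulate_swimmer(
    rng: np.random.Generator, start: np.ndarray, n_frames: int,
    speed_um_s: float, persistence: float, dt: float,
) -> np.ndarray:
    if n_frames == 1:
        return start[None, :].copy()
    heading_sd = (1.0 - persistence) * math.pi
    headings = rng.uniform(0.0, 2.0 * math.pi) + np.concatenate(
        ([0.0], np.cumsum(rng.normal(0.0, heading_sd, size=n_frames - 2)))
    )
    steps = speed_um_s * dt * np.column_stack([np.cos(headings), np.sin(headings)])
    positions = np.empty((n_frames, 2))
    positions[0] = start
    positions[1:] = start + np.cumsum(steps, axis=0)
    return positions


def simulate_tracks(
    mixture: MotilityMixture,
    geometry: FieldGeometry | None = None,
    capture_duration_s: float = 0.75,
    frame_rate_hz: float = 60.0,
    seed: int | None = None,
) -> GroundTruth:
    """Simulate one capture's ground-truth trajectories.

    The cell count is Poisson with mean ``concentration x field volume``;
    cells leaving the field keep the partial track up to their exit frame.
    Results are fully reproducible for a given seed (``seed`` argument wins
    over ``mixture.seed``).
    """
    geometry = geometry or FieldGeometry()
    if not capture_duration_s > 0:
        raise ValueError(f"capture duration must be positive, got {capture_duration_s}")
    if not frame_rate_hz > 0:
        raise ValueError(f"frame rate must be positive, got {frame_rate_hz}")
    mixture.validate()
    rng = np.random.default_rng(seed if seed is not None else mixture.seed)
    n_frames = int(round(capture_duration_s * frame_rate_hz))
    if n_frames < 1:
        raise ValueError("capture too short for a single frame")
    dt = 1.0 / frame_rate_hz

    n_cells = int(rng.poisson(mixture.concentration_cells_ml * geometry.volume_ml))
    fracs = mixture.fractions
    labels = rng.choice(
        CLASS_NAMES, size=n_cells, p=[fracs[name] for name in CLASS_NAMES]
    )
    drift = np.asarray(mixture.drift_velocity_um_s, dtype=float)
    drift_path = np.outer(np.arange(n_frames) * dt, drift)

    cells: list[TruthCell] = []
    for cell_id in range(n_cells):
        label = str(labels[cell_id])
        area = rng.uniform(*mixture.head_area_range_um2)
        start = np.array(
            [rng.uniform(0.0, geometry.width_um), rng.uniform(0.0, geometry.height_um)]
        )
        if label == "static":
            limit = _STATIC_RADIUS_FRACTION * 0.8 * head_diameter(area)
            positions = _simulate_static(
                rng, start, n_frames, mixture.static_jitter_sd_um, limit
            )
        else:
            speed = rng.uniform(*mixture.speed_range_um_s[label])
            persistence = mixture.directional_persistence[label]
            positions = _simulate_swimmer(rng, start, n_frames, speed, persistence, dt)
        positions = positions + drift_path

        inside = (
            (positions[:, 0] >= 0.0)
            & (positions[:, 0] <= geometry.width_um)
            & (positions[:, 1] >= 0.0)
            & (positions[:, 1] <= geometry.height_um)
        )
        n_keep = int(np.argmin(inside)) if not inside.all() else n_frames
        if n_keep == 0:  # cannot happen: start is inside, kept for safety
            continue
        cells.append(
            TruthCell(
                cell_id=cell_id,
                motility_class=label,
                head_area_um2=float(area),
                frames=np.arange(n_keep),
                positions=positions[:n_keep].copy(),
            )
        )
    return GroundTruth(
        cells=cells, geometry=geometry, frame_rate_hz=frame_rate_hz, n_frames=n_frames
    )


@dataclass(frozen=True)
class OpticsSpec:
    """Rendering parameters for synthetic darkfield-style frames.

    Intensities are on a [0, saturation] scale; ``spot_amplitude`` is the
    peak height above background, and a cell's area above the half-maximum
    level equals its head area.  Blooms are static saturated discs strictly
    larger than the maximum head size.
    """

    spot_amplitude: float = 0.7
    background: float = 0.1
    noise_sd: float = 0.02
    microns_per_pixel: float = 1.0
    bloom_count: int = 0
    bloom_radius_um: float = 10.0
    saturation: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.spot_amplitude < self.background:
            raise ValueError(
                f"spot_amplitude ({self.spot_amplitude}) must be at least the "
                f"background level ({self.background})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")
        if self.bloom_count < 0:
            raise ValueError("bloom_count cannot be negative")

    @property
    def half_max_level(self) -> float:
        """Intensity level at which rendered spot area equals head area."""
        return self.background + 0.5 * self.spot_amplitude


def _spot_sigma_um(head_area_um2: float) -> float:
    # Radius at half maximum equals the head radius: sigma = r / sqrt(2 ln 2).
    radius = math.sqrt(head_area_um2 / math.pi)
    return radius / math.sqrt(2.0 * math.log(2.0))


def render_frames(truth: GroundTruth, optics: OpticsSpec | None = None) -> FrameStack:
    """Render a ground truth into a grayscale frame stack.

    Raises :class:`CalibrationError` when a head's Gaussian sigma falls below
    one pixel at the requested calibration (spots would be unresolvable).
    """
    optics = optics or OpticsSpec()
    mpp = optics.microns_per_pixel
    width_px = max(1, int(round(truth.geometry.width_um / mpp)))
    height_px = max(1, int(round(truth.geometry.height_um / mpp)))
    rng = np.random.default_rng(optics.seed)

    for cell in truth.cells:
        if _spot_sigma_um(cell.head_area_um2) / mpp < 1.0:
            raise CalibrationError(
                f"cell {cell.cell_id}: spot sigma "
                f"{_spot_sigma_um(cell.head_area_um2) / mpp:.3f} px is below 1 px; "
                "calibration too coarse for this head size"
            )

    # pixel centres in µm
    xs = (np.arange(width_px) + 0.5) * mpp
    ys = (np.arange(height_px) + 0.5) * mpp

    bloom_centres = np.column_stack(
        [
            rng.uniform(0.0, truth.geometry.width_um, size=optics.bloom_count),
            rng.uniform(0.0, truth.geometry.height_um, size=optics.bloom_count),
        ]
    )

    frames = np.full(
        (truth.n_frames, height_px, width_px), optics.background, dtype=float
    )
    for frame_index in range(truth.n_frames):
        img = frames[frame_index]
        for cell, position in truth.cells_in_frame(frame_index):
            sigma = _spot_sigma_um(cell.head_area_um2)
            extent = 5.0 * sigma
            x0, y0 = position
            j_lo = max(0, int((x0 - extent) / mpp))
            j_hi = min(width_px, int((x0 + extent) / mpp) + 1)
            i_lo = max(0, int((y0 - extent) / mpp))
            i_hi = min(height_px, int((y0 + extent) / mpp) + 1)
            if j_lo >= j_hi or i_lo >= i_hi:
                continue
            dx = xs[j_lo:j_hi] - x0
            dy = ys[i_lo:i_hi] - y0
            gauss = np.exp(
                -(dy[:, None] ** 2 + dx[None, :] ** 2) / (2.0 * sigma**2)
            )
            img[i_lo:i_hi, j_lo:j_hi] += optics.spot_amplitude * gauss
        if optics.noise_sd > 0:
            img += rng.normal(0.0, optics.noise_sd, size=img.shape)
        np.clip(img, 0.0, optics.saturation, out=img)
        for bx, by in bloom_centres:  # blooms: static, exactly saturated
            dx = xs - bx
            dy = ys - by
            disc = (dy[:, None] ** 2 + dx[None, :] ** 2) <= optics.bloom_radius_um**2
            img[disc] = optics.saturation

    return FrameStack(
        frames=frames, microns_per_pixel=mpp, frame_rate_hz=truth.frame_rate_hz
    )


def truth_detections(truth: GroundTruth):
    """Ideal detections straight from the truth (bypassing rendering).

    Useful for testing linking and kinematics in isolation from segmentation.
    """
    from .detection import Detection

    detections = []
    for frame_index in range(truth.n_frames):
        for cell, position in truth.cells_in_frame(frame_index):
            detections.append(
                Detection(
                    frame_index=frame_index,
                    x_um=float(position[0]),
                    y_um=float(position[1]),
                    area_um2=cell.head_area_um2,
                    mean_intensity=1.0,
                )
            )
    return detections


@dataclass
class FertParams:
    """Generator parameters for a synthetic fertilisation dataset.

    Success follows ``intercept + slope x log10(cells/egg)`` plus Gaussian
    noise, clipped to [0, 100]; doses are log-uniform over ``ratio_range``
    (log10 cells per egg).
    """

    intercept: float = 0.0
    slope: float = 20.0
    noise_sd: float = 8.0
    n_records: int = 24
    ratio_range: tuple[float, float] = (1.5, 4.5)  # log10 cells/egg
    egg_range: tuple[int, int] = (28, 90)
    motile_concentration_cells_ml: float = 2.0e6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_records < 3:
            raise ValueError(f"n_records must be at least 3, got {self.n_records}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")
        lo, hi = self.ratio_range
        if not lo < hi:
            raise ValueError(f"ratio_range is empty: ({lo}, {hi})")
        if not (1 <= self.egg_range[0] <= self.egg_range[1]):
            raise ValueError(f"egg_range invalid: {self.egg_range}")
        if not self.motile_concentration_cells_ml > 0:
            raise ValueError("motile concentration must be positive")


_FERT_TREATMENTS = ("fresh", "fresh+DMSO", "cryo")


def synth_fert_dataset(params: FertParams) -> list[FertilisationRecord]:
    """Generate fertilisation records with a known log-linear dose response.

    The dose volume is back-solved so each record's motile-cells-per-egg
    ratio reproduces the sampled value exactly; cleavage counts are the
    success percentage rounded onto the egg count.
    """
    from .fertilisation import required_volume

    rng = np.random.default_rng(params.seed)
    log_ratios = rng.uniform(*params.ratio_range, size=params.n_records)
    noise = (
        rng.normal(0.0, params.noise_sd, size=params.n_records)
        if params.noise_sd > 0
        else np.zeros(params.n_records)
    )
    success = np.clip(params.intercept + params.slope * log_ratios + noise, 0.0, 100.0)
    eggs = rng.integers(params.egg_range[0], params.egg_range[1] + 1,
                        size=params.n_records)
    records = []
    for i in range(params.n_records):
        n_eggs = int(eggs[i])
        ratio = 10.0 ** float(log_ratios[i])
        volume = required_volume(
            ratio, params.motile_concentration_cells_ml, n_eggs
        )
        n_cleaved = int(round(success[i] / 100.0 * n_eggs))
        records.append(
            FertilisationRecord(
                sample_id=f"cross_{i:03d}",
                motile_concentration_cells_ml=params.motile_concentration_cells_ml,
                sperm_volume_ul=volume,
                n_eggs=n_eggs,
                n_cleaved=n_cleaved,
                n_uncleaved=n_eggs - n_cleaved,
                treatment=_FERT_TREATMENTS[i % len(_FERT_TREATMENTS)],
            )
        )
    return records
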