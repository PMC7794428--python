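"""End-to-end analysis: mask -> segment -> link -> kinematics -> classify ->
quantify -> QC, over one or more captured fields of a sample.

Concentration uses the mean number of detections per frame (robust to track
fragmentation); motility percentages use only tracks long enough to score
(``min_track_frames``).  The whole run is deterministic for fixed inputs and
settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as casa_io
from .detection import (
    Detection,
    FrameStack,
    build_artifact_mask,
    head_diameter,
    segment_stack,
)
from .kinematics import TrackKinematics, analyse_track
from .qc import (
    FLAG_SPLIT_RISK,
    FLAG_STALE_WELL,
    FLAG_UNIFORM_FLOW,
    check_capture,
    check_staleness,
    check_working_range,
    detect_uniform_flow,
)
from .quantitation import (
    FieldResult,
    SampleResult,
    aggregate_sample,
    field_concentration,
)
from .settings import CasaSettings
from .tracking import Track, link_detections, split_risk_report

logger = logging.getLogger("coralcasa")

__all__ = ["FieldAnalysis", "analyze_field", "analyze_sample", "analyze_paths", "batch_report"]


@dataclass
class FieldAnalysis:
    """Everything computed for one field."""

    field_id: str
    detections: list[Detection]
    tracks: list[Track]
    kinematics: list[TrackKinematics]  # classified, long-enough tracks only
    result: FieldResult
    n_frames: int


def _field_from_detections(
    field_id: str,
    detections: list[Detection],
    n_frames: int,
    field_area_um2: float,
    settings: CasaSettings,
) -> FieldAnalysis:
    tracks = link_detections(detections, settings.cell_travel_max_um)
    kinematics: list[TrackKinematics] = []
    for track in tracks:
        if len(track) < max(2, settings.min_track_frames):
            continue
        kinematics.append(analyse_track(track, settings))
    counts = {"static": 0, "slow": 0, "motile": 0, "progressive": 0}
    for kin in kinematics:
        counts[kin.motility_class] += 1
    mean_per_frame = len(detections) / n_frames if n_frames else 0.0
    concentration = field_concentration(
        mean_per_frame,
        field_area_um2,
        settings.chamber_depth_um,
        settings.dilution_factor,
    )
    result = FieldResult(
        field_id=field_id,
        class_counts=counts,
        field_area_um2=field_area_um2,
        chamber_depth_um=settings.chamber_depth_um,
        concentration_cells_ml=concentration,
        dilution=settings.dilution_factor,
        mean_detections_per_frame=mean_per_frame,
    )
    return FieldAnalysis(
        field_id=field_id,
        detections=detections,
        tracks=tracks,
        kinematics=kinematics,
        result=result,
        n_frames=n_frames,
    )


def analyze_field(
    stack: FrameStack, settings: CasaSettings, field_id: str = "field_0"
) -> FieldAnalysis:
    """Run the per-field pipeline on a frame stack."""
    mask = build_artifact_mask(stack, settings) if stack.n_frames >= 5 else None
    detections = segment_stack(stack, settings, mask=mask)
    width_um, height_um = stack.field_size_um
    return _field_from_detections(
        field_id, detections, stack.n_frames, width_um * height_um, settings
    )


def analyze_sample(
    fields: list[FieldAnalysis],
    settings: CasaSettings,
    sample_id: str = "sample",
    treatment: str | None = None,
    load_time: float | None = None,
    capture_time: float | None = None,
) -> tuple[SampleResult, dict]:
    """Aggregate analysed fields into a sample result with full QC.

    Returns the sample result and a QC diagnostics dictionary (drift vector,
    staleness, max trackable VCL).
    """
    if not fields:
        raise ValueError("analyze_sample needs at least one analysed field")
    result = aggregate_sample(
        [f.result for f in fields],
        sample_id=sample_id,
        treatment=treatment,
        min_fields=settings.min_fields,
        min_cells=settings.min_cells,
    )
    flags = set(result.qc_flags)
    flags |= check_capture(
        len(fields), result.n_cells, settings.min_fields, settings.min_cells
    )
    flags |= check_working_range(
        result.total_concentration_cells_ml, settings.working_range, settings.ideal_range
    )
    all_tracks = [t for f in fields for t in f.tracks if len(t) >= 2]
    drift = detect_uniform_flow(
        all_tracks, settings.frame_rate_hz, settings.drift_threshold_um_s
    )
    if drift.flagged:
        flags.add(FLAG_UNIFORM_FLOW)
    staleness = check_staleness(load_time, capture_time, settings.stale_well_max_s)
    if staleness.flagged:
        flags.add(FLAG_STALE_WELL)
    split = split_risk_report(settings)
    if split.at_risk:
        flags.add(FLAG_SPLIT_RISK)

    result.qc_flags = tuple(sorted(flags))
    diagnostics = {
        "drift_um_s": list(drift.drift_um_s),
        "drift_magnitude_um_s": drift.magnitude_um_s,
        "drift_n_tracks": drift.n_tracks,
        "staleness_status": staleness.status,
        "elapsed_since_load_s": staleness.elapsed_s,
        "max_trackable_vcl_um_s": split.max_trackable_vcl_um_s,
    }
    for key, value in sorted(
        {**diagnostics, "qc_flags": list(result.qc_flags)}.items()
    ):
        logger.info("qc %s = %r", key, value)
    return result, diagnostics


def _load_field(path: Path, settings: CasaSettings) -> tuple[list[Detection], int, float]:
    """Load one field input (TIFF/AVI stack or detections CSV).

    Returns (detections, n_frames, field_area_um2).  For CSV input the frame
    count is inferred from the largest frame index and the field area from
    the capture defaults (detections carry no field geometry).
    """
    if path.suffix.lower() == ".csv":
        detections = casa_io.detections_from_csv(path)
        n_frames = max((d.frame_index for d in detections), default=-1) + 1
        n_frames = max(n_frames, settings.n_frames)
        area = 640.0 * 480.0  # default field; override via stack input for real geometry
        return detections, n_frames, area
    stack = casa_io.read_stack(
        path, settings.microns_per_pixel, settings.frame_rate_hz
    )
    mask = build_artifact_mask(stack, settings) if stack.n_frames >= 5 else None
    detections = segment_stack(stack, settings, mask=mask)
    width_um, height_um = stack.field_size_um
    return detections, stack.n_frames, width_um * height_um


def analyze_paths(
    paths: list[str | Path],
    settings: CasaSettings,
    out_dir: str | Path | None = None,
    sample_id: str = "sample",
    treatment: str | None = None,
) -> tuple[SampleResult, dict]:
    """Analyse a sample from per-field input files and write artifacts.

    Each path is one field (multi-page TIFF, AVI, or detections CSV).
    Artifacts written to ``out_dir``: ``tracks.csv``, ``kinematics.csv``,
    ``sample.json``.
    """
    if not paths:
        raise ValueError("no input fields given")
    for key, value in sorted(settings.to_dict().items()):
        logger.info("setting %s = %r", key, value)
    fields: list[FieldAnalysis] = []
    for index, raw in enumerate(paths):
        path = Path(raw)
        detections, n_frames, area = _load_field(path, settings)
        fields.append(
            _field_from_detections(
                f"field_{index}", detections, n_frames, area, settings
            )
        )
        logger.info(
            "field %d (%s): %d detections, %d tracks",
            index,
            path.name,
            len(fields[-1].detections),
            len(fields[-1].tracks),
        )
    result, diagnostics = analyze_sample(
        fields, settings, sample_id=sample_id, treatment=treatment
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_tracks, all_kin = [], []
        offset = 0
        for f in fields:
            for t in f.tracks:
                t.track_id += offset
            for k in f.kinematics:
                all_kin.append(
                    type(k)(**{**k.__dict__, "track_id": k.track_id + offset})
                )
            all_tracks.extend(f.tracks)
            offset += len(f.tracks)
        casa_io.tracks_to_csv(all_tracks, out / "tracks.csv")
        casa_io.kinematics_to_csv(all_kin, out / "kinematics.csv")
        casa_io.sample_result_to_json(
            result,
            out / "sample.json",
            qc_diagnostics=diagnostics,
            settings_dict=settings.to_dict(),
        )
    return result, diagnostics


def batch_report(results: list[SampleResult]):
    """One comparison row per sample, ordered by sample id.

    Percentages are reported to 0.1 and concentrations to 3 significant
    figures; QC flags are joined into one column.
    """
    import pandas as pd

    def _sig3(value: float | None) -> float | None:
        if value is None:
            return None
        return float(np.format_float_positional(
            value, precision=3, unique=False, fractional=False
        ))

    def _pct(value: float | None) -> float | None:
        return None if value is None else round(value, 1)

    rows = []
    for r in sorted(results, key=lambda s: s.sample_id):
        rows.append(
            {
                "sample_id": r.sample_id,
                "treatment": r.treatment,
                "n_fields": r.n_fields,
                "n_cells": r.n_cells,
                "total_motility_pct": _pct(r.total_motility_pct),
                "progressive_motility_pct": _pct(r.progressive_motility_pct),
                "total_concentration_cells_ml": _sig3(r.total_concentration_cells_ml),
                "motile_concentration_cells_ml": _sig3(r.motile_concentration_cells_ml),
                "qc_flags": ";".join(r.qc_flags),
            }
        )
    return pd.DataFrame(rows)
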