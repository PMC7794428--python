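"""File I/O: TIFF/AVI stacks and the CSV/JSON interchange formats.

Conventions (also printed in every CSV header comment): frames are
0-indexed, the coordinate origin is the field's top-left corner with y
increasing downward, and all lengths are in µm after calibration.

Frame stacks are stored as multi-page grayscale TIFF; pixel intensities are
normalised to [0, 1] floats on read (dividing by the dtype's full scale) and
written as 16-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import Detection, FrameStack
from .fertilisation import FertilisationRecord
from .kinematics import TrackKinematics
from .quantitation import SampleResult
from .simulator import GroundTruth
from .tracking import Track

__all__ = [
    "read_stack",
    "write_stack",
    "detections_to_csv",
    "detections_from_csv",
    "tracks_to_csv",
    "kinematics_to_csv",
    "truth_to_csv",
    "fert_records_to_csv",
    "fert_records_from_csv",
    "sample_result_to_json",
]

_HEADER_COMMENT = "# frames 0-indexed; origin top-left, y down; lengths in um\n"


def read_stack(
    path: str | Path,
    microns_per_pixel: float,
    frame_rate_hz: float,
    load_time: float | None = None,
    capture_time: float | None = None,
) -> FrameStack:
    """Read a multi-page TIFF (or AVI) into a normalised float stack."""
    path = Path(path)
    if path.suffix.lower() in (".avi", ".mp4", ".mov"):
        frames = _read_video(path)
    else:
        frames = tifffile.imread(path)
        frames = np.asarray(frames)
        if frames.ndim == 2:
            frames = frames[None, :, :]
        if frames.ndim == 4:  # RGB pages -> luminance
            frames = frames.mean(axis=-1)
        if np.issubdtype(frames.dtype, np.integer):
            frames = frames.astype(float) / np.iinfo(frames.dtype).max
        else:
            frames = frames.astype(float)
    return FrameStack(
        frames=frames,
        microns_per_pixel=microns_per_pixel,
        frame_rate_hz=frame_rate_hz,
        load_time=load_time,
        capture_time=capture_time,
    )


def _read_video(path: Path) -> np.ndarray:
    try:
        import imageio.v2 as imageio
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("reading video files requires the 'imageio' package") from exc
    try:
        reader = imageio.get_reader(str(path))
    except Exception as exc:  # pragma: no cover - missing ffmpeg plugin
        raise RuntimeError(f"could not open video {path}: {exc}") from exc
    frames = []
    for frame in reader:
        arr = np.asarray(frame, dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=-1)
        frames.append(arr / 255.0)
    reader.close()
    if not frames:
        raise ValueError(f"video {path} contains no frames")
    return np.stack(frames)


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as multi-page 16-bit TIFF (intensities clipped to [0, 1])."""
    scaled = np.clip(stack.frames, 0.0, 1.0)
    tifffile.imwrite(Path(path), (scaled * 65535.0).round().astype(np.uint16))


# -- CSV interchange -----------------------------------------------------


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_HEADER_COMMENT)
        df.to_csv(fh, index=False)


def detections_to_csv(detections: list[Detection], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (d.frame_index, d.x_um, d.y_um, d.area_um2, d.mean_intensity)
            for d in detections
        ],
        columns=["frame", "x_um", "y_um", "area_um2", "intensity"],
    )
    _write_csv(df, path)


def detections_from_csv(path: str | Path) -> list[Detection]:
    df = pd.read_csv(path, comment="#")
    return [
        Detection(
            frame_index=int(row.frame),
            x_um=float(row.x_um),
            y_um=float(row.y_um),
            area_um2=float(row.area_um2),
            mean_intensity=float(getattr(row, "intensity", 0.0)),
        )
        for row in df.itertuples(index=False)
    ]


def tracks_to_csv(tracks: list[Track], path: str | Path) -> None:
    rows = [
        (t.track_id, d.frame_index, d.x_um, d.y_um, d.area_um2)
        for t in tracks
        for d in t.detections
    ]
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "area_um2"])
    _write_csv(df, path)


def kinematics_to_csv(kinematics: list[TrackKinematics], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                k.track_id,
                k.vcl_um_s,
                k.vap_um_s,
                k.vsl_um_s,
                k.max_excursion_um,
                k.motility_class,
            )
            for k in kinematics
        ],
        columns=["track_id", "vcl", "vap", "vsl", "max_excursion_um", "class"],
    )
    _write_csv(df, path)


def truth_to_csv(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth trajectories: one row per cell per frame."""
    rows = [
        (cell.cell_id, cell.motility_class, cell.head_area_um2, int(frame), x, y)
        for cell in truth.cells
        for frame, (x, y) in zip(cell.frames, cell.positions)
    ]
    df = pd.DataFrame(
        rows, columns=["cell_id", "class", "head_area_um2", "frame", "x_um", "y_um"]
    )
    _write_csv(df, path)


def fert_records_to_csv(records: list[FertilisationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                r.sample_id,
                r.treatment,
                r.motile_concentration_cells_ml,
                r.sperm_volume_ul,
                r.n_eggs,
                r.n_cleaved,
                r.n_uncleaved,
            )
            for r in records
        ],
        columns=[
            "sample_id",
            "treatment",
            "motile_concentration_cells_ml",
            "sperm_volume_ul",
            "n_eggs",
            "n_cleaved",
            "n_uncleaved",
        ],
    )
    _write_csv(df, path)


def fert_records_from_csv(path: str | Path) -> list[FertilisationRecord]:
    df = pd.read_csv(path, comment="#")

    def _maybe_int(value) -> int | None:
        return None if pd.isna(value) else int(value)

    return [
        FertilisationRecord(
            sample_id=str(row.sample_id),
            motile_concentration_cells_ml=float(row.motile_concentration_cells_ml),
            sperm_volume_ul=float(row.sperm_volume_ul),
            n_eggs=int(row.n_eggs),
            n_cleaved=_maybe_int(row.n_cleaved),
            n_uncleaved=_maybe_int(row.n_uncleaved),
            treatment=None if pd.isna(row.treatment) else str(row.treatment),
        )
        for row in df.itertuples(index=False)
    ]


def sample_result_to_json(
    result: SampleResult,
    path: str | Path,
    qc_diagnostics: dict | None = None,
    settings_dict: dict | None = None,
) -> None:
    """Serialise a sample result (plus QC diagnostics) as deterministic JSON.

    Keys are sorted and no timestamps are embedded, so identical analyses
    produce byte-identical files.
    """
    payload = {"sample": dataclasses.asdict(result)}
    payload["conventions"] = "frames 0-indexed; origin top-left, y down; lengths in um"
    if qc_diagnostics is not None:
        payload["qc_diagnostics"] = qc_diagnostics
    if settings_dict is not None:
        payload["settings"] = settings_dict
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
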