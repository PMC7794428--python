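"""Frame-to-frame linking of detections into tracks.

Linking is an optimal bipartite assignment between consecutive frames:
among candidate pairs whose displacement does not exceed ``cell_travel_max``,
the match maximising the number of links and then minimising total distance
is chosen (Hungarian algorithm with a large penalty on infeasible pairs).
The displacement bound is closed: a step of exactly ``cell_travel_max``
still links, so with a 5 µm bound at 60 Hz the fastest unbroken straight
path moves at 300 µm/s and anything faster splits into multiple tracks.

Tracks never span a missed frame and are never re-joined: a detection gap
always starts a new track.  This reproduces the documented failure mode of
an over-tight travel bound (genuine fast paths split apart).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection
from .settings import CasaSettings

__all__ = ["Track", "SplitRiskReport", "link_detections", "split_risk_report"]

_INFEASIBLE = 1.0e12


@dataclass
class Track:
    """A linked trajectory: detections at strictly consecutive frames."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [d.frame_index for d in self.detections]
        if frames and frames != list(range(frames[0], frames[0] + len(frames))):
            raise ValueError(f"track {self.track_id} frames not consecutive: {frames}")

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame_index for d in self.detections], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in µm."""
        return np.array([(d.x_um, d.y_um) for d in self.detections], dtype=float)

    @property
    def displacements(self) -> np.ndarray:
        """(n-1, 2) per-step displacement vectors in µm."""
        return np.diff(self.positions, axis=0)

    @property
    def mean_head_area_um2(self) -> float:
        return float(np.mean([d.area_um2 for d in self.detections]))


def link_detections(
    detections: list[Detection], cell_travel_max_um: float
) -> list[Track]:
    """Link detections into tracks under the maximum-travel constraint.

    ``detections`` may arrive in any order; they are grouped by frame index.
    Output is deterministic: per frame pair the assignment minimises total
    distance (infeasible pairs excluded), and track ids follow creation
    order (frame, then input order within the frame).
    """
    if not cell_travel_max_um > 0:
        raise ValueError("cell_travel_max_um must be positive")
    if not detections:
        return []

    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame_index, []).append(det)
    first, last = min(by_frame), max(by_frame)

    tracks: list[Track] = []
    open_tracks: list[Track] = []  # tracks whose tail is at the previous frame

    def _start(dets: list[Detection]) -> list[Track]:
        fresh = []
        for det in dets:
            track = Track(track_id=len(tracks))
            track.detections.append(det)
            tracks.append(track)
            fresh.append(track)
        return fresh

    open_tracks = _start(by_frame.get(first, []))
    for frame in range(first + 1, last + 1):
        current = by_frame.get(frame, [])
        if not open_tracks or not current:
            open_tracks = _start(current)
            continue
        tails = np.array(
            [(t.detections[-1].x_um, t.detections[-1].y_um) for t in open_tracks]
        )
        heads = np.array([(d.x_um, d.y_um) for d in current])
        dist = np.hypot(
            tails[:, None, 0] - heads[None, :, 0],
            tails[:, None, 1] - heads[None, :, 1],
        )
        cost = np.where(dist <= cell_travel_max_um, dist, _INFEASIBLE)
        rows, cols = linear_sum_assignment(cost)
        matched_cols: set[int] = set()
        next_open: list[Track] = []
        for r, c in zip(rows, cols):
            if dist[r, c] <= cell_travel_max_um:
                open_tracks[r].detections.append(current[c])
                next_open.append(open_tracks[r])
                matched_cols.add(c)
        unmatched = [d for j, d in enumerate(current) if j not in matched_cols]
        next_open.extend(_start(unmatched))
        open_tracks = next_open

    return tracks


@dataclass(frozen=True)
class SplitRiskReport:
    """Fastest unbroken velocity under the configured travel bound."""

    cell_travel_max_um: float
    frame_rate_hz: float
    max_trackable_vcl_um_s: float
    expected_max_speed_um_s: float
    at_risk: bool
    message: str


def split_risk_report(settings: CasaSettings) -> SplitRiskReport:
    """Report the maximum trackable VCL and whether fast swimmers may split.

    The maximum trackable curvilinear velocity is
    ``cell_travel_max × frame_rate``; faster genuine paths are falsely
    disconnected, so operators must check analysed captures when the bound
    sits below the species' expected top speed.
    """
    max_vcl = settings.cell_travel_max_um * settings.frame_rate_hz
    at_risk = max_vcl < settings.expected_max_speed_um_s
    if at_risk:
        message = (
            f"max trackable VCL {max_vcl:.6g} µm/s is below the expected top "
            f"speed {settings.expected_max_speed_um_s:.6g} µm/s; genuine fast "
            "paths may be split — visually check analysed captures"
        )
    else:
        message = (
            f"max trackable VCL {max_vcl:.6g} µm/s covers the expected top "
            f"speed {settings.expected_max_speed_um_s:.6g} µm/s"
        )
    return SplitRiskReport(
        cell_travel_max_um=settings.cell_travel_max_um,
        frame_rate_hz=settings.frame_rate_hz,
        max_trackable_vcl_um_s=max_vcl,
        expected_max_speed_um_s=settings.expected_max_speed_um_s,
        at_risk=at_risk,
        message=message,
    )
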