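"""Per-track kinematic metrics and motility classification.

VCL is the raw point-to-point path length over the track duration, VAP the
length of a centred moving-average smoothing of the path (window shrinks
symmetrically at the ends, so the first and last points are preserved and
VSL <= VAP holds), and VSL the net start-to-end displacement over duration.

Classification: a track is *static* when it never leaves a radius of
``static_width_multiplier`` x head diameter around its first position during
the capture; otherwise it is binned by its classification velocity
(VAP by default): below the slow bound -> slow, above the progressive bound
-> progressive, in between (bounds inclusive) -> motile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .settings import CasaSettings
from .tracking import Track

__all__ = [
    "TrackKinematics",
    "MOTILITY_CLASSES",
    "compute_kinematics",
    "classify_track",
    "analyse_track",
]

MOTILITY_CLASSES = ("static", "slow", "motile", "progressive")


@dataclass(frozen=True)
class TrackKinematics:
    track_id: int
    vcl_um_s: float
    vap_um_s: float
    vsl_um_s: float
    max_excursion_um: float
    duration_s: float
    n_frames: int
    mean_head_area_um2: float
    motility_class: str | None = None


def _smooth_path(positions: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with symmetric window shrinkage at the ends."""
    half = window // 2
    n = len(positions)
    out = np.empty_like(positions)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = positions[i - k : i + k + 1].mean(axis=0)
    return out


def _path_length(positions: np.ndarray) -> float:
    steps = np.diff(positions, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def compute_kinematics(
    track: Track, settings: CasaSettings, enforce_min_frames: bool = True
) -> TrackKinematics:
    """Compute VCL/VAP/VSL and maximum excursion for one track.

    Tracks shorter than two frames are rejected; with ``enforce_min_frames``
    (the default) tracks shorter than ``settings.min_track_frames`` are also
    rejected — they carry too little of the capture to score motility.
    """
    n = len(track)
    if n < 2:
        raise ValueError(f"track {track.track_id} has {n} frame(s); need at least 2")
    if enforce_min_frames and n < settings.min_track_frames:
        raise ValueError(
            f"track {track.track_id} has {n} frames, below min_track_frames="
            f"{settings.min_track_frames}"
        )
    positions = track.positions
    duration = (n - 1) / settings.frame_rate_hz
    vcl = _path_length(positions) / duration
    smoothed = _smooth_path(positions, settings.smoothing_frames)
    vap = _path_length(smoothed) / duration
    vsl = float(np.hypot(*(positions[-1] - positions[0]))) / duration
    offsets = positions - positions[0]
    max_excursion = float(np.hypot(offsets[:, 0], offsets[:, 1]).max())
    return TrackKinematics(
        track_id=track.track_id,
        vcl_um_s=vcl,
        vap_um_s=vap,
        vsl_um_s=vsl,
        max_excursion_um=max_excursion,
        duration_s=duration,
        n_frames=n,
        mean_head_area_um2=track.mean_head_area_um2,
    )


def classify_track(
    kin: TrackKinematics, head_diameter_um: float, settings: CasaSettings
) -> str:
    """Assign exactly one motility class to a track's kinematics."""
    if not head_diameter_um > 0:
        raise ValueError("head_diameter_um must be positive")
    if kin.max_excursion_um < settings.static_width_multiplier * head_diameter_um:
        return "static"
    velocity = {
        "vap": kin.vap_um_s,
        "vcl": kin.vcl_um_s,
        "vsl": kin.vsl_um_s,
    }[settings.classification_velocity]
    if velocity < settings.slow_bound_um_s:
        return "slow"
    if velocity > settings.progressive_bound_um_s:
        return "progressive"
    return "motile"


def analyse_track(
    track: Track, settings: CasaSettings, enforce_min_frames: bool = True
) -> TrackKinematics:
    """Kinematics plus class in one call (head diameter from mean head area)."""
    from .detection import head_diameter

    kin = compute_kinematics(track, settings, enforce_min_frames=enforce_min_frames)
    cls = classify_track(kin, head_diameter(kin.mean_head_area_um2), settings)
    return replace(kin, motility_class=cls)
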