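"""Per-frame segmentation of sperm heads and masking of static bright artefacts.

Heads are the only thing segmented (tail detection is permanently off);
candidate components are gated by head area and may be vetoed by an artefact
mask built from pixels that stay bright through the whole capture.

Coordinate conventions, used everywhere downstream:

* frames are 0-indexed;
* the origin is the top-left corner of the field, y increases downward;
* the centre of pixel ``(row, col)`` sits at
  ``x = (col + 0.5) * microns_per_pixel``, ``y = (row + 0.5) * microns_per_pixel``;
* all positions and areas are in µm / µm².
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .settings import CasaSettings

__all__ = [
    "FrameStack",
    "Detection",
    "BlankFrameWarning",
    "segment_frame",
    "segment_stack",
    "build_artifact_mask",
    "head_diameter",
]


class BlankFrameWarning(UserWarning):
    """A frame had zero dynamic range; it contributes no detections."""


@dataclass
class FrameStack:
    """An ordered stack of grayscale frames plus calibration metadata.

    ``load_time`` / ``capture_time`` (seconds, any common epoch) are optional
    well-handling timestamps consumed by the staleness QC check.
    """

    frames: np.ndarray  # (n_frames, height, width), float
    microns_per_pixel: float
    frame_rate_hz: float
    load_time: float | None = None
    capture_time: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n, h, w), got shape {self.frames.shape}")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(width, height) of the imaged field in µm."""
        h, w = self.shape_px
        return w * self.microns_per_pixel, h * self.microns_per_pixel


@dataclass(frozen=True)
class Detection:
    """One segmented head in one frame (intensity-weighted centroid, µm)."""

    frame_index: int
    x_um: float
    y_um: float
    area_um2: float
    mean_intensity: float


def head_diameter(area_um2: float) -> float:
    """Circular-equivalent head diameter ``2 * sqrt(area / pi)`` in µm."""
    if not area_um2 > 0:
        raise ValueError(f"head area must be positive, got {area_um2}")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def segment_frame(
    frame: np.ndarray,
    settings: CasaSettings,
    mask: np.ndarray | None = None,
    frame_index: int = 0,
) -> list[Detection]:
    """Segment bright connected components of one frame into detections.

    The threshold is Otsu's unless ``settings.fixed_threshold`` is set.
    Components outside the head-area gate, or overlapping ``mask``, are
    discarded whole.  A blank frame (zero dynamic range) emits a
    :class:`BlankFrameWarning` and returns an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if mask is not None and mask.shape != frame.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frame.shape}"
        )
    if frame.max() == frame.min():
        warnings.warn(
            f"frame {frame_index} has zero dynamic range; no detections",
            BlankFrameWarning,
            stacklevel=2,
        )
        return []
    threshold = (
        settings.fixed_threshold
        if settings.fixed_threshold is not None
        else threshold_otsu(frame)
    )
    binary = frame > threshold
    labels, n_labels = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n_labels == 0:
        return []
    mpp = settings.microns_per_pixel

    # vectorised per-component sums (much faster than per-region properties)
    flat = labels.ravel()
    weights = frame.ravel()
    area_px = np.bincount(flat, minlength=n_labels + 1)[1:]
    total_intensity = np.bincount(flat, weights=weights, minlength=n_labels + 1)[1:]
    rows, cols = np.indices(frame.shape)
    row_sum = np.bincount(flat, weights=weights * rows.ravel(), minlength=n_labels + 1)[1:]
    col_sum = np.bincount(flat, weights=weights * cols.ravel(), minlength=n_labels + 1)[1:]

    area_um2 = area_px * mpp * mpp
    keep = (area_um2 >= settings.min_head_area_um2) & (
        area_um2 <= settings.max_head_area_um2
    )
    if mask is not None and mask.any():
        overlap = np.bincount(labels[mask].ravel(), minlength=n_labels + 1)[1:]
        keep &= overlap == 0

    out: list[Detection] = []
    for idx in np.flatnonzero(keep):
        row = row_sum[idx] / total_intensity[idx]
        col = col_sum[idx] / total_intensity[idx]
        out.append(
            Detection(
                frame_index=frame_index,
                x_um=(col + 0.5) * mpp,
                y_um=(row + 0.5) * mpp,
                area_um2=float(area_um2[idx]),
                mean_intensity=float(total_intensity[idx] / area_px[idx]),
            )
        )
    return out


def segment_stack(
    stack: FrameStack,
    settings: CasaSettings,
    mask: np.ndarray | None = None,
) -> list[Detection]:
    """Segment every frame of a stack; detections are ordered by frame."""
    detections: list[Detection] = []
    for index in range(stack.n_frames):
        detections.extend(
            segment_frame(stack.frames[index], settings, mask=mask, frame_index=index)
        )
    return detections


def build_artifact_mask(stack: FrameStack, settings: CasaSettings) -> np.ndarray:
    """Mask static saturated artefacts (dust/salt blooms) for exclusion.

    A pixel is a bloom candidate when its temporal *minimum* exceeds a high
    percentile of the stack's global intensity distribution, i.e. it is bright
    in every frame.  Candidate components no larger than the head-area gate
    are ignored — genuinely static cells also persist in place and must not
    be masked; blooms are by construction bigger than any head.  Surviving
    components are dilated by one (maximum) head diameter.
    """
    if stack.n_frames < 5:
        raise ValueError(
            f"artifact mask needs at least 5 frames, got {stack.n_frames}"
        )
    temporal_min = stack.frames.min(axis=0)
    # subsample the stack for the global percentile: statistically equivalent
    # and much cheaper than sorting every pixel of every frame
    flat = stack.frames.ravel()
    stride = max(1, flat.size // 1_000_000)
    cutoff = np.percentile(flat[::stride], settings.mask_percentile)
    # guard against sparse scenes where the percentile degenerates to the
    # background level: a bloom candidate must also be brighter than the
    # midpoint of the stack's dynamic range
    lo, hi = float(stack.frames.min()), float(stack.frames.max())
    cutoff = max(cutoff, 0.5 * (lo + hi))
    candidates = temporal_min > cutoff
    if not candidates.any():
        return np.zeros_like(candidates, dtype=bool)
    mpp = settings.microns_per_pixel
    labels = measure.label(candidates, connectivity=2)
    mask = np.zeros_like(candidates, dtype=bool)
    for region in measure.regionprops(labels):
        if region.area * mpp * mpp > settings.max_head_area_um2:
            rows, cols = region.coords[:, 0], region.coords[:, 1]
            mask[rows, cols] = True
    if mask.any():
        radius_px = max(1, int(math.ceil(head_diameter(settings.max_head_area_um2) / mpp)))
        mask = morphology.dilation(mask, morphology.disk(radius_px))
    return mask
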