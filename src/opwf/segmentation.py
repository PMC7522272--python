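"""ROI cropping, vessel/tissue segmentation and region-mean series extraction.

Segmentation operates on the time-mean MBR map so the masks are constant over
the acquisition, mirroring a single composite-map segmentation.  Coordinates
are 0-based, half-open, row-major; the ROI is specified in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

from .errors import BoundsError, DegenerateSegmentationError

__all__ = [
    "MBRFrameSequence",
    "ROIRect",
    "RegionMasks",
    "crop_roi",
    "segment_vessel_tissue",
    "extract_region_waveforms",
]

REGIONS = ("MA", "MV", "MT")


@dataclass(frozen=True)
class MBRFrameSequence:
    """Time-stamped stack of 2-D MBR maps (arbitrary units).

    ``frames`` has shape ``(n_frames, height, width)`` with
    ``n_frames = round(frame_rate_hz * acquisition_s)``.
    """

    frames: np.ndarray
    frame_rate_hz: float
    acquisition_s: float
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (time, row, col) stack")
        if frames.shape[0] != round(self.frame_rate_hz * self.acquisition_s):
            raise ValueError(
                "frame count must equal round(frame_rate_hz * acquisition_s)"
            )
        if np.any(frames < 0):
            raise ValueError("MBR values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def mean_map(self) -> np.ndarray:
        """Time-mean MBR map (the composite map segmentation works on)."""
        return self.frames.mean(axis=0)


@dataclass(frozen=True)
class ROIRect:
    """Rectangular region of interest: 0-based, half-open pixel bounds."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI height and width must be positive")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")


@dataclass(frozen=True)
class RegionMasks:
    """Disjoint vessel/tissue masks partitioning the ROI."""

    vessel: np.ndarray
    tissue: np.ndarray

    def __post_init__(self) -> None:
        vessel = np.asarray(self.vessel, dtype=bool)
        tissue = np.asarray(self.tissue, dtype=bool)
        object.__setattr__(self, "vessel", vessel)
        object.__setattr__(self, "tissue", tissue)
        if vessel.shape != tissue.shape:
            raise ValueError("vessel and tissue masks must share a shape")
        if np.any(vessel & tissue):
            raise DegenerateSegmentationError("vessel and tissue masks overlap")
        if not np.all(vessel | tissue):
            raise DegenerateSegmentationError("masks do not cover the ROI")
        if not vessel.any() or not tissue.any():
            raise DegenerateSegmentationError("empty vessel or tissue mask")

    @property
    def vessel_fraction(self) -> float:
        return float(self.vessel.mean())


def crop_roi(seq: MBRFrameSequence, rect: ROIRect) -> MBRFrameSequence:
    """Crop every frame to ``rect``; acquisition metadata is preserved."""
    n_rows, n_cols = seq.frame_shape
    if rect.row0 + rect.height > n_rows or rect.col0 + rect.width > n_cols:
        raise BoundsError(
            f"ROI {rect} exceeds frame bounds {(n_rows, n_cols)}"
        )
    sub = seq.frames[
        :, rect.row0 : rect.row0 + rect.height, rect.col0 : rect.col0 + rect.width
    ]
    valid = None
    if seq.valid_mask is not None:
        valid = seq.valid_mask[
            rect.row0 : rect.row0 + rect.height, rect.col0 : rect.col0 + rect.width
        ]
    return MBRFrameSequence(
        frames=sub.copy(),
        frame_rate_hz=seq.frame_rate_hz,
        acquisition_s=seq.acquisition_s,
        valid_mask=valid,
    )


def segment_vessel_tissue(
    mean_map: np.ndarray,
    method: str = "otsu",
    quantile_q: float = 0.2,
) -> RegionMasks:
    """Threshold the time-mean map into vessel (bright) and tissue pixels.

    ``method='otsu'`` uses Otsu's threshold; ``method='quantile'`` marks the
    top ``quantile_q`` fraction of pixels as vessel.

    Raises
    ------
    DegenerateSegmentationError
        For a constant map, or when a threshold leaves either mask empty.
    """
    mean_map = np.asarray(mean_map, dtype=float)
    if not np.all(np.isfinite(mean_map)):
        raise DegenerateSegmentationError("mean map contains non-finite values")
    if np.ptp(mean_map) == 0:
        raise DegenerateSegmentationError(
            "constant map: no threshold separates vessel from tissue"
        )
    if method == "otsu":
        # Otsu seed + intermeans refinement: plain Otsu can land on the edge
        # of a wide empty gap between sharply peaked classes.
        thr = float(threshold_otsu(mean_map))
        for _ in range(100):
            low, high = mean_map[mean_map <= thr], mean_map[mean_map > thr]
            if low.size == 0 or high.size == 0:
                break
            new_thr = (low.mean() + high.mean()) / 2.0
            if abs(new_thr - thr) < 1e-9:
                break
            thr = new_thr
        vessel = mean_map > thr
    elif method == "quantile":
        if not 0 < quantile_q < 1:
            raise ValueError("quantile_q must lie in (0, 1)")
        vessel = mean_map >= np.quantile(mean_map, 1.0 - quantile_q)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    return RegionMasks(vessel=vessel, tissue=~vessel)


def extract_region_waveforms(
    seq: MBRFrameSequence, masks: RegionMasks
) -> dict[str, np.ndarray]:
    """Region-mean MBR series for MA (whole ROI), MV (vessel), MT (tissue).

    The MA series is exactly the pixel-count-weighted mean of MV and MT.
    """
    if masks.vessel.shape != seq.frame_shape:
        raise ValueError("mask shape does not match frame shape")
    flat = seq.frames.reshape(seq.n_frames, -1)
    mv = flat[:, masks.vessel.ravel()].mean(axis=1)
    mt = flat[:, masks.tissue.ravel()].mean(axis=1)
    ma = flat.mean(axis=1)
    return {"MA": ma, "MV": mv, "MT": mt}
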