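"""Background-statistics segmentation and per-well quantification.

Drug-bearing cellular structures are segmented by intensity alone: a pixel
belongs to a cluster if its leakage-corrected intensity strictly exceeds the
mean background fluorescence of cell-free culture media plus ``k_sigma``
(default 3) sample standard deviations, measured from regions of interest
outside the cluster boundaries. The per-well readout is the arithmetic mean
intensity over segmented pixels, so it reflects drug accumulated within
cellular structures rather than the whole well.

Thresholds are held numerically constant across the pre-/post-activation
pair of a well so that any change in segmented mean intensity reflects
genuine drug redistribution rather than a moving segmentation boundary;
this is asserted downstream by provenance checks.

Wells whose segmentation is empty are reported as below detection
(an error the caller converts to a missing value), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptySegmentationError, InsufficientBackgroundError
from .frames import ROI, ImageFrame, roi_area, roi_slice, validate_roi

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "WellMeasurement",
    "default_background_rois",
    "estimate_background_threshold",
    "segment_clusters",
    "quantify_well",
]

MIN_BACKGROUND_PIXELS = 25


@dataclass
class SegmentationParams:
    """Threshold-estimation settings for one well."""

    background_rois: list[ROI]
    k_sigma: float = 3.0
    floor_negative: bool = True
    min_object_size: int = 0  # optional cleanup, off by default

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if not self.background_rois:
            raise ValueError("at least one background ROI is required")
        if sum(roi_area(r) for r in self.background_rois) < MIN_BACKGROUND_PIXELS:
            raise ValueError(
                f"background ROIs must cover >= {MIN_BACKGROUND_PIXELS} pixels"
            )


@dataclass
class SegmentationResult:
    threshold: float
    mask: np.ndarray
    n_pixels: int
    mean_intensity: float | None
    sd_intensity: float | None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.n_pixels != int(self.mask.sum()):
            raise ValueError("n_pixels inconsistent with mask")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass
class WellMeasurement:
    """One quantified (well, channel, timepoint) observation with provenance."""

    well_id: str
    channel: str
    timepoint: str
    concentration: float
    mean_signal: float
    n_pixels: int
    threshold_used: float
    background_level: float = 0.0  # media background mean used for the threshold
    cell_model: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")


def default_background_rois(
    shape: tuple[int, int],
    *,
    margin_frac: float = 0.2,
    box_frac: float = 0.09,
) -> list[ROI]:
    """Fallback background ROIs: the four corner regions of the well ROI.

    The well's analysable region is the frame inset by ``margin_frac`` of its
    smaller dimension (clear of rim reflections); the four corner squares of
    that region sit outside the central zone where spheroid clusters form.
    """
    ny, nx = shape
    m = round(margin_frac * min(ny, nx))
    b = max(5, round(box_frac * min(ny, nx)))
    rois: list[ROI] = [
        (m, m + b, m, m + b),
        (m, m + b, nx - m - b, nx - m),
        (ny - m - b, ny - m, m, m + b),
        (ny - m - b, ny - m, nx - m - b, nx - m),
    ]
    for r in rois:
        validate_roi(r, shape)
    return rois


def default_well_roi(shape: tuple[int, int], *, margin_frac: float = 0.2) -> ROI:
    """Central analysable region of a per-well frame (rim excluded)."""
    ny, nx = shape
    m = round(margin_frac * min(ny, nx))
    return (m, ny - m, m, nx - m)


def _background_pixels(frame: ImageFrame, params: SegmentationParams) -> np.ndarray:
    vals = []
    for roi in params.background_rois:
        validate_roi(roi, frame.shape)
        vals.append(frame.pixels[roi_slice(roi)].ravel())
    pooled = np.concatenate(vals)
    if pooled.size < MIN_BACKGROUND_PIXELS:
        raise InsufficientBackgroundError(
            f"only {pooled.size} background pixels; need >= {MIN_BACKGROUND_PIXELS}"
        )
    return pooled


def background_statistics(
    frame: ImageFrame, params: SegmentationParams
) -> tuple[float, float]:
    """(mean, sample SD) of the pooled background-ROI pixels."""
    bg = _background_pixels(frame, params)
    if params.floor_negative:
        bg = np.maximum(bg, 0.0)
    sd = float(bg.std(ddof=1)) if bg.size > 1 else 0.0
    return float(bg.mean()), sd


def estimate_background_threshold(
    frame: ImageFrame, params: SegmentationParams
) -> float:
    """mean(background) + k_sigma × sample-SD(background), pooled over ROIs."""
    mean, sd = background_statistics(frame, params)
    return mean + params.k_sigma * sd


def segment_clusters(
    frame: ImageFrame,
    threshold: float,
    *,
    floor_negative: bool = True,
    min_object_size: int = 0,
    within_roi: ROI | None = None,
) -> SegmentationResult:
    """Pixels strictly above the threshold, with summary statistics.

    Negative corrected intensities are floored at zero before comparison
    (they are noise around true zero, by construction of the correction).
    Ties at the threshold count as background. An empty mask is a valid
    result. ``min_object_size`` optionally removes connected components
    smaller than the given pixel count (off by default — the base method is
    pure intensity thresholding). ``within_roi`` restricts segmentation to
    the well's analysable region (excluding, e.g., the rim of the well,
    where plastic reflections concentrate).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pixels = np.maximum(frame.pixels, 0.0) if floor_negative else frame.pixels
    mask = pixels > threshold
    if within_roi is not None:
        validate_roi(within_roi, frame.shape)
        region = np.zeros(frame.shape, dtype=bool)
        region[roi_slice(within_roi)] = True
        mask &= region
    if min_object_size > 0 and mask.any():
        labels, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_object_size) + 1
        mask = np.isin(labels, keep)
    n_pixels = int(mask.sum())
    if n_pixels > 0:
        sel = frame.pixels[mask]
        mean = float(sel.mean())
        sd = float(sel.std(ddof=1)) if n_pixels > 1 else 0.0
    else:
        mean = sd = None
    return SegmentationResult(
        threshold=float(threshold),
        mask=mask,
        n_pixels=n_pixels,
        mean_intensity=mean,
        sd_intensity=sd,
    )


def quantify_well(
    frame: ImageFrame,
    seg: SegmentationResult,
    *,
    concentration: float,
    background_level: float = 0.0,
    cell_model: str = "",
) -> WellMeasurement:
    """Mean corrected intensity over the segmented pixels of one well.

    Raises :class:`EmptySegmentationError` when nothing was segmented: the
    well must be reported as below detection, not as zero signal.
    """
    if seg.n_pixels < 1 or seg.mean_intensity is None:
        raise EmptySegmentationError(
            f"well {frame.well_id!r} ({frame.channel}, {frame.timepoint}): "
            "no pixels above threshold"
        )
    return WellMeasurement(
        well_id=frame.well_id,
        channel=frame.channel,
        timepoint=frame.timepoint,
        concentration=concentration,
        mean_signal=seg.mean_intensity,
        n_pixels=seg.n_pixels,
        threshold_used=seg.threshold,
        background_level=background_level,
        cell_model=cell_model,
    )
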