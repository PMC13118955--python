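"""Image frames and region-of-interest primitives.

An :class:`ImageFrame` is a 2-D grid of detector counts plus the acquisition
metadata the pipeline needs to route it: which fluorophore channel it belongs
to (doxorubicin ``dox`` ~590 nm or porphyrin ``pop`` ~720 nm), whether it was
taken through the fluorescence emission filter, the matched neutral-density
(ND) reference filter, or with the shutter closed (dark), and at which
timepoint relative to the activation-light exposure.

ROIs are half-open rectangles ``(row0, row1, col0, col1)`` in 0-based,
row-major pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DimensionError

CHANNELS = ("dox", "pop")
FILTER_ROLES = ("fluorescence", "nd_reference", "dark")
TIMEPOINTS = ("pre_activation", "post_activation", "calibration")

#: half-open rectangle (row0, row1, col0, col1)
ROI = tuple[int, int, int, int]


@dataclass
class ImageFrame:
    """A single acquired (or simulated) camera frame with routing metadata."""

    pixels: np.ndarray
    channel: str = "dox"
    filter_role: str = "fluorescence"
    timepoint: str = "calibration"
    well_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DimensionError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.filter_role not in FILTER_ROLES:
            raise ValueError(
                f"unknown filter_role {self.filter_role!r}; expected one of {FILTER_ROLES}"
            )
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ImageFrame":
        """Copy of this frame with new pixel data and identical metadata."""
        return replace(self, pixels=np.asarray(pixels, dtype=float))


def check_conformable(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise DimensionError(f"grid shapes differ: {a.shape} vs {b.shape}")


def validate_roi(roi: ROI, shape: tuple[int, int]) -> None:
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"ROI {roi} not inside frame of shape {shape}")


def roi_slice(roi: ROI) -> tuple[slice, slice]:
    r0, r1, c0, c1 = roi
    return slice(r0, r1), slice(c0, c1)


def rois_overlap(a: ROI, b: ROI) -> bool:
    return a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]


def roi_area(roi: ROI) -> int:
    return (roi[1] - roi[0]) * (roi[3] - roi[2])
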