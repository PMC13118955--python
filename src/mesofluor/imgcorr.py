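"""Calibration and excitation-leakage correction.

Excitation light and well-plate reflections bleed through the emission
filter and contaminate the fluorescence channel. A reference image taken
through a neutral-density filter of matched optical density, under identical
excitation, sees (to a good approximation) only that leakage. After dark
subtraction the fluorescence-channel leakage is a linearly scaled version of
the ND image, so the scaling factor is estimated by ordinary least squares
through the origin over fluorophore-free (water-filled) calibration wells::

    alpha = sum_xy F(x,y) * ND(x,y)  /  sum_xy ND(x,y)**2

and the correction subtracts the scaled, spatially weighted leakage
estimate::

    F_corr(x,y) = F(x,y) - alpha * ND(x,y) * M(x,y)

where the mask ``M`` in [0, 1] is the max-normalised (lightly smoothed) ND
signal. Weighting by ``M`` concentrates the subtraction where leakage is
actually present and prevents overcorrection of low-leakage regions.

Negative corrected intensities are preserved here — clipping before
averaging would bias low-signal wells upward — and floored only at the
segmentation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateCalibrationError
from .frames import ImageFrame, check_conformable

__all__ = [
    "ImageFrame",
    "CalibrationSet",
    "LeakageModel",
    "subtract_dark",
    "mean_dark_frame",
    "estimate_leakage_alpha",
    "build_leakage_mask",
    "correct_leakage",
]


@dataclass
class CalibrationSet:
    """Frames acquired before an imaging session at one filter configuration.

    ``water_well_pairs`` are (fluorescence, ND) frames of water-filled wells
    (zero true fluorophore), the regression set for the leakage factor.
    ``drug_only_frames`` image drug-filled wells without cells, quantifying
    extracellular drug fluorescence. ``planted_leakage_fraction`` is attached
    by the simulator for recovery tests; it is ``None`` for real data.
    """

    dark_frames: list[ImageFrame]
    water_well_pairs: list[tuple[ImageFrame, ImageFrame]]
    drug_only_frames: list[ImageFrame] = field(default_factory=list)
    planted_leakage_fraction: float | None = None

    def __post_init__(self) -> None:
        if len(self.dark_frames) < 1:
            raise ValueError("calibration requires at least one dark frame")
        for f, nd in self.water_well_pairs:
            check_conformable(f.pixels, nd.pixels)


@dataclass
class LeakageModel:
    """Fitted leakage model: scaling factor, spatial mask and diagnostics."""

    alpha: float
    mask: np.ndarray
    fit_r_squared: float
    n_calibration_wells: int
    per_well_alpha: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError("alpha must be finite and nonnegative")
        m = np.asarray(self.mask, dtype=float)
        if (m < 0).any() or (m > 1).any():
            raise ValueError("mask values must lie in [0, 1]")
        self.mask = m
        if not 0 <= self.fit_r_squared <= 1:
            raise ValueError("fit_r_squared must lie in [0, 1]")

    def session_alpha_mean(self) -> float:
        return float(np.mean(self.per_well_alpha)) if self.per_well_alpha else self.alpha

    def session_alpha_sd(self) -> float:
        if len(self.per_well_alpha) < 2:
            return 0.0
        return float(np.std(self.per_well_alpha, ddof=1))

    def to_report(self) -> dict:
        return {
            "alpha": self.alpha,
            "fit_r_squared": self.fit_r_squared,
            "n_calibration_wells": self.n_calibration_wells,
            "per_well_alpha": list(self.per_well_alpha),
            "session_alpha_mean": self.session_alpha_mean(),
            "session_alpha_sd": self.session_alpha_sd(),
            "mask_summary": {
                "min": float(self.mask.min()),
                "max": float(self.mask.max()),
                "mean": float(self.mask.mean()),
            },
        }


def subtract_dark(frame: ImageFrame, dark: ImageFrame) -> ImageFrame:
    """Pixelwise dark subtraction; negatives are preserved, not clipped."""
    if dark.filter_role != "dark":
        raise ValueError(f"dark frame has filter_role {dark.filter_role!r}, expected 'dark'")
    check_conformable(frame.pixels, dark.pixels)
    return frame.with_pixels(frame.pixels - dark.pixels)


def mean_dark_frame(dark_frames: list[ImageFrame]) -> ImageFrame:
    """Pixelwise mean of the available dark frames for one filter config."""
    if not dark_frames:
        raise ValueError("no dark frames provided")
    stack = np.stack([d.pixels for d in dark_frames])
    return dark_frames[0].with_pixels(stack.mean(axis=0))


def _alpha_through_origin(f: np.ndarray, nd: np.ndarray) -> float:
    denom = float((nd * nd).sum())
    if denom == 0.0:
        raise DegenerateCalibrationError("sum of ND**2 is zero: blank ND channel")
    return float((f * nd).sum() / denom)


def estimate_leakage_alpha(
    calibration: CalibrationSet,
    *,
    mask_smooth_sigma: float = 2.0,
) -> LeakageModel:
    """Fit the leakage scaling factor over a calibration session.

    All water-well pairs are dark-subtracted (using the per-filter mean dark
    frame) and pooled into a single through-origin OLS fit; the closed form
    is the ratio of the pooled cross-moment to the pooled ND second moment.
    Per-well factors are recorded as well, to report session mean ± SD.

    ``fit_r_squared`` is the uncentred R² of the through-origin fit,
    ``1 - sum((F - alpha ND)**2) / sum(F**2)`` — the standard convention for
    regression without an intercept.

    The spatial mask is built from the pixelwise mean of the dark-subtracted
    calibration ND frames (see :func:`build_leakage_mask`).
    """
    if len(calibration.water_well_pairs) == 0:
        raise ValueError("calibration contains no water-well pairs")
    dark = mean_dark_frame(calibration.dark_frames)
    f_all, nd_all = [], []
    per_well = []
    for f_frame, nd_frame in calibration.water_well_pairs:
        f = subtract_dark(f_frame, dark).pixels
        nd = subtract_dark(nd_frame, dark).pixels
        per_well.append(_alpha_through_origin(f, nd))
        f_all.append(f)
        nd_all.append(nd)
    f_pool = np.concatenate([a.ravel() for a in f_all])
    nd_pool = np.concatenate([a.ravel() for a in nd_all])
    alpha = _alpha_through_origin(f_pool, nd_pool)

    ss_res = float(((f_pool - alpha * nd_pool) ** 2).sum())
    ss_tot = float((f_pool**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    mean_nd = np.mean(np.stack(nd_all), axis=0)
    mask = build_leakage_mask(
        ImageFrame(pixels=mean_nd, filter_role="nd_reference"),
        smooth_sigma=mask_smooth_sigma,
    )
    return LeakageModel(
        alpha=alpha,
        mask=mask,
        fit_r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_calibration_wells=len(calibration.water_well_pairs),
        per_well_alpha=per_well,
    )


def build_leakage_mask(
    nd_frame: ImageFrame, *, smooth_sigma: float = 2.0
) -> np.ndarray:
    """Spatially weighted mask from the normalised ND signal.

    ``M = clip(smooth(ND) / max(smooth(ND)), 0, 1)``, where ``smooth`` is a
    Gaussian blur of SD ``smooth_sigma`` pixels (0 disables smoothing, which
    otherwise suppresses single-pixel noise spikes from dominating the
    normalisation). M is 1 at the brightest leakage location and decays
    toward 0 where leakage is negligible. An all-zero ND frame yields an
    all-zero mask with a warning — there is no leakage to correct.
    """
    nd = np.asarray(nd_frame.pixels, dtype=float)
    smoothed = ndimage.gaussian_filter(nd, smooth_sigma) if smooth_sigma > 0 else nd
    peak = float(smoothed.max())
    if peak <= 0:
        warnings.warn(
            "ND frame has no positive signal; returning an all-zero mask",
            stacklevel=2,
        )
        return np.zeros_like(nd)
    return np.clip(smoothed / peak, 0.0, 1.0)


def correct_leakage(
    f_frame: ImageFrame,
    nd_frame: ImageFrame,
    model: LeakageModel,
    *,
    mask: np.ndarray | None = None,
) -> ImageFrame:
    """Masked leakage subtraction: ``F - alpha * ND * M``.

    Both frames must already be dark-subtracted. ``mask`` overrides the
    model's stored mask (e.g. to rebuild M from this acquisition's own ND
    frame); by default the session mask fitted from calibration is used.
    Negative results are preserved.
    """
    check_conformable(f_frame.pixels, nd_frame.pixels)
    m = model.mask if mask is None else np.asarray(mask, dtype=float)
    check_conformable(f_frame.pixels, m)
    corrected = f_frame.pixels - model.alpha * nd_frame.pixels * m
    return f_frame.with_pixels(corrected)
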