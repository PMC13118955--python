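"""In-memory analysis chain: calibrate → correct → segment → quantify → fit.

This is the computational core shared by the orchestration layer
(:mod:`mesofluor.plateio`), the numbered analysis drivers, the test suite
and the acceptance script. It operates on lists of
:class:`~mesofluor.frames.ImageFrame` plus per-channel calibration sets and
a well → concentration layout, with no file I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosestat import (
    BleachingDelta,
    DoseResponseFit,
    fit_dose_response,
    fold_change,
    photobleaching_delta,
)
from .errors import EmptySegmentationError, InsufficientDataError
from .frames import ImageFrame
from .imgcorr import (
    CalibrationSet,
    LeakageModel,
    correct_leakage,
    estimate_leakage_alpha,
    mean_dark_frame,
    subtract_dark,
)
from .segquant import (
    SegmentationParams,
    WellMeasurement,
    background_statistics,
    default_background_rois,
    default_well_roi,
    quantify_well,
    segment_clusters,
)

log = logging.getLogger("mesofluor")

__all__ = ["AnalysisResult", "analyze_frames", "measurements_table"]


@dataclass
class AnalysisResult:
    """All per-stage outputs of one pipeline run."""

    leakage_models: dict[str, LeakageModel]
    measurements: list[WellMeasurement]
    missing: list[tuple[str, str, str]]  # (well, channel, timepoint) below detection
    corrected_frames: list[ImageFrame] = field(default_factory=list)
    dose_fits: dict[str, DoseResponseFit] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)
    bleaching: list[BleachingDelta] = field(default_factory=list)

    def measurements_frame(self) -> pd.DataFrame:
        return measurements_table(self.measurements)


def measurements_table(measurements: list[WellMeasurement]) -> pd.DataFrame:
    """Per-well measurements as a tidy table, stably ordered."""
    rows = [
        {
            "well_id": m.well_id,
            "channel": m.channel,
            "timepoint": m.timepoint,
            "concentration": m.concentration,
            "threshold": m.threshold_used,
            "background_level": m.background_level,
            "n_pixels": m.n_pixels,
            "mean_signal": m.mean_signal,
            "cell_model": m.cell_model,
        }
        for m in measurements
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "well_id", "channel", "timepoint", "concentration",
            "threshold", "background_level", "n_pixels", "mean_signal", "cell_model",
        ],
    )
    return df.sort_values(["channel", "timepoint", "well_id"], kind="stable").reset_index(
        drop=True
    )


def _index_frames(frames: list[ImageFrame]):
    idx: dict[tuple[str, str, str, str], ImageFrame] = {}
    for fr in frames:
        idx[(fr.well_id, fr.channel, fr.filter_role, fr.timepoint)] = fr
    return idx


def analyze_frames(
    frames: list[ImageFrame],
    calibration: dict[str, CalibrationSet],
    concentrations: dict[str, float],
    *,
    k_sigma: float = 3.0,
    mask_smooth_sigma: float = 2.0,
    min_object_size: int = 0,
    background_rois=None,
    analysis_wells: set[str] | None = None,
    roles: dict[str, str] | None = None,
    fit_timepoints: dict[str, str] | None = None,
    cell_model: str = "",
    keep_corrected: bool = False,
) -> AnalysisResult:
    """Run the full correction/segmentation/quantification/fitting chain.

    Parameters
    ----------
    frames:
        Experiment frames; each imaged (well, channel, timepoint) must have
        a ``fluorescence`` frame and a paired ``nd_reference`` frame.
    calibration:
        channel → :class:`CalibrationSet` (dark frames + water wells).
    concentrations:
        well_id → administered concentration (μg/mL). Only wells listed here
        are analysed.
    k_sigma:
        Multiplier on the background SD for the segmentation threshold.
    background_rois:
        Explicit background ROIs; ``None`` uses the four-corner fallback of
        each well frame.
    analysis_wells:
        Restrict quantification to these wells (default: every well in
        ``concentrations``).
    roles:
        well_id → ``treatment`` / ``control`` / ``blank``. Control and blank
        wells are still quantified, but dose-response fits, fold changes and
        bleaching deltas use treatment wells only. ``None`` treats every
        well as treatment.
    fit_timepoints:
        channel → timepoint used for the dose-response fit; defaults to
        post-activation for ``dox`` (release readout) and pre-activation
        for ``pop`` (carrier localisation readout).

    Returns
    -------
    AnalysisResult with per-channel leakage models, per-well measurements,
    dose-response fits, fold changes and porphyrin bleaching deltas. Wells
    whose segmentation is empty are recorded in ``missing`` and excluded
    from fits (never imputed as zero).
    """
    if fit_timepoints is None:
        fit_timepoints = {"dox": "post_activation", "pop": "pre_activation"}

    models = {
        ch: estimate_leakage_alpha(cal, mask_smooth_sigma=mask_smooth_sigma)
        for ch, cal in calibration.items()
    }
    for ch, model in models.items():
        log.info(
            "channel %s: alpha=%.4f (session mean %.4f ± %.4f, R²=%.4f, n=%d)",
            ch, model.alpha, model.session_alpha_mean(),
            model.session_alpha_sd(), model.fit_r_squared, model.n_calibration_wells,
        )

    dark_means = {ch: mean_dark_frame(cal.dark_frames) for ch, cal in calibration.items()}
    idx = _index_frames(frames)
    combos = sorted(
        {
            (fr.well_id, fr.channel, fr.timepoint)
            for fr in frames
            if fr.filter_role == "fluorescence" and fr.well_id in concentrations
        }
    )
    if analysis_wells is not None:
        combos = [c for c in combos if c[0] in analysis_wells]

    measurements: list[WellMeasurement] = []
    missing: list[tuple[str, str, str]] = []
    corrected_kept: list[ImageFrame] = []
    # threshold and background level held constant across timepoints of a
    # (well, channel): changes in segmented mean then reflect genuine drug
    # redistribution, not a moving boundary
    threshold_cache: dict[tuple[str, str], tuple[float, float]] = {}

    # process pre-activation first so its threshold is the one cached
    tp_order = {"pre_activation": 0, "post_activation": 1, "calibration": 2}
    combos.sort(key=lambda c: (c[0], c[1], tp_order[c[2]]))

    for well_id, channel, timepoint in combos:
        if channel not in models:
            raise KeyError(f"no calibration for channel {channel!r}")
        f_frame = idx[(well_id, channel, "fluorescence", timepoint)]
        nd_frame = idx.get((well_id, channel, "nd_reference", timepoint))
        if nd_frame is None:
            raise KeyError(
                f"well {well_id} ({channel}, {timepoint}): missing ND reference frame"
            )
        dark = dark_means[channel]
        f = subtract_dark(f_frame, dark)
        nd = subtract_dark(nd_frame, dark)
        corrected = correct_leakage(f, nd, models[channel])
        if keep_corrected:
            corrected_kept.append(corrected)

        rois = background_rois or default_background_rois(corrected.shape)
        params = SegmentationParams(
            background_rois=list(rois), k_sigma=k_sigma, min_object_size=min_object_size
        )
        key = (well_id, channel)
        if key not in threshold_cache:
            bg_mean, bg_sd = background_statistics(corrected, params)
            threshold_cache[key] = (bg_mean + k_sigma * bg_sd, bg_mean)
        threshold, background_level = threshold_cache[key]

        seg = segment_clusters(
            corrected, threshold,
            min_object_size=min_object_size,
            within_roi=default_well_roi(corrected.shape),
        )
        try:
            m = quantify_well(
                corrected, seg,
                concentration=concentrations[well_id],
                background_level=background_level,
                cell_model=cell_model,
            )
        except EmptySegmentationError:
            log.warning(
                "well %s (%s, %s) below detection; dropped from fits",
                well_id, channel, timepoint,
            )
            missing.append((well_id, channel, timepoint))
            continue
        measurements.append(m)

    result = AnalysisResult(
        leakage_models=models,
        measurements=measurements,
        missing=missing,
        corrected_frames=corrected_kept,
    )

    def is_treatment(well_id: str) -> bool:
        return roles is None or roles.get(well_id, "treatment") == "treatment"

    for channel, timepoint in fit_timepoints.items():
        pts = [
            m for m in measurements
            if m.channel == channel and m.timepoint == timepoint
            and m.concentration > 0 and is_treatment(m.well_id)
        ]
        if not pts:
            continue
        try:
            fit = fit_dose_response(pts)
        except InsufficientDataError:
            log.warning("channel %s: too few wells for a dose-response fit", channel)
            continue
        result.dose_fits[channel] = fit
        try:
            result.fold_changes[channel] = fold_change(fit)
        except Exception:  # non-positive baseline: leave absent
            pass

    pre = [
        m for m in measurements
        if m.channel == "pop" and m.timepoint == "pre_activation"
        and is_treatment(m.well_id)
    ]
    post_by_key = {
        (m.well_id, m.channel): m
        for m in measurements
        if m.channel == "pop" and m.timepoint == "post_activation"
        and is_treatment(m.well_id)
    }
    paired_pre = [m for m in pre if (m.well_id, m.channel) in post_by_key]
    paired_post = [post_by_key[(m.well_id, m.channel)] for m in paired_pre]
    if paired_pre:
        result.bleaching = photobleaching_delta(paired_pre, paired_post)

    return result
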