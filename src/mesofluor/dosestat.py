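"""Statistical layer: dose-response calibration, agreement, release, bleaching.

Covers the quantitative readouts of the imaging workflow:

- linear dose-response calibration of mean well signal against administered
  concentration (OLS with intercept, centred R²);
- fold change between the highest and the lowest nonzero concentration;
- cross-platform method agreement between the imaging readout and a bulk
  plate reader (OLS regression R² plus Bland–Altman bias, 95% limits of
  agreement, and their confidence intervals);
- pre/post-activation porphyrin photobleaching deltas;
- serum-stability release fraction,
  ``(F_final - F_initial) / (F_X100 - F_initial) × 100%``, where F_X100 is
  the fully dequenched fluorescence after Triton X-100 lysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    PairingError,
    ProvenanceError,
    UndefinedFoldChangeError,
    UndefinedReleaseError,
)
from .segquant import WellMeasurement

__all__ = [
    "DoseResponseFit",
    "AgreementReport",
    "ReleaseMeasurement",
    "BleachingDelta",
    "fit_dose_response",
    "fold_change",
    "compare_platforms",
    "photobleaching_delta",
    "release_fraction",
]


@dataclass
class DoseResponseFit:
    concentrations: list[float]
    mean_signals: list[float]
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.mean_signals):
            raise ValueError("concentrations and mean_signals differ in length")
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must lie in [0, 1]")

    def to_report(self) -> dict:
        return {
            "concentrations": list(self.concentrations),
            "mean_signals": list(self.mean_signals),
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
        }


@dataclass
class AgreementReport:
    """Bland–Altman + regression summary of platform A vs platform B.

    Differences are ``a - b``; a negative bias means platform A reads lower.
    """

    n_pairs: int
    bias: float
    percent_bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    loa_width: float
    bias_ci: tuple[float, float]
    loa_ci_lower: tuple[float, float]
    loa_ci_upper: tuple[float, float]
    regression_r_squared: float

    def to_report(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "bias": self.bias,
            "percent_bias": self.percent_bias,
            "sd_diff": self.sd_diff,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "loa_width": self.loa_width,
            "bias_ci": list(self.bias_ci),
            "loa_ci_lower": list(self.loa_ci_lower),
            "loa_ci_upper": list(self.loa_ci_upper),
            "regression_r_squared": self.regression_r_squared,
        }


@dataclass
class ReleaseMeasurement:
    """Fluorescence triplet of a serum-incubation release assay."""

    f_initial: float
    f_final: float
    f_triton: float


@dataclass
class BleachingDelta:
    concentration: float
    pre_mean: float
    post_mean: float
    absolute_decrease: float
    fractional_decrease: float

    def to_report(self) -> dict:
        return self.__dict__.copy()


def fit_dose_response(measurements: list[WellMeasurement]) -> DoseResponseFit:
    """OLS (with intercept) of mean well signal on administered concentration.

    Requires at least three distinct concentrations with non-missing
    signals. R² is the centred convention; a constant response returns
    R² = 0 (zero explained variance) rather than undefined.
    """
    pts = [
        (m.concentration, m.mean_signal)
        for m in measurements
        if m.mean_signal is not None and np.isfinite(m.mean_signal)
    ]
    if len(pts) < 3 or len({c for c, _ in pts}) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct concentrations, got {len({c for c, _ in pts})}"
        )
    x = np.array([c for c, _ in pts], dtype=float)
    y = np.array([s for _, s in pts], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all concentrations identical")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return DoseResponseFit(
        concentrations=x.tolist(),
        mean_signals=y.tolist(),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
    )


def fold_change(fit: DoseResponseFit) -> float:
    """Signal at the highest concentration over the lowest nonzero one."""
    pairs = [(c, s) for c, s in zip(fit.concentrations, fit.mean_signals) if c > 0]
    if not pairs:
        raise UndefinedFoldChangeError("no nonzero concentrations")
    c_lo, s_lo = min(pairs, key=lambda p: p[0])
    c_hi, s_hi = max(pairs, key=lambda p: p[0])
    if s_lo <= 0:
        raise UndefinedFoldChangeError(
            f"baseline signal at {c_lo} μg/mL is non-positive ({s_lo})"
        )
    return float(s_hi / s_lo)


def compare_platforms(platform_a, platform_b) -> AgreementReport:
    """Bland–Altman agreement between paired readings of the same wells.

    ``d_i = a_i - b_i``; bias = mean(d); limits of agreement =
    bias ± 1.96 × sample SD(d). The bias CI uses the t distribution (n is
    small in practice); LoA CIs use the standard Bland–Altman approximate
    variance ``sd²(1/n + 1.96²/(2(n-1)))``. ``percent_bias`` normalises the
    bias by the grand mean of pairwise means. ``regression_r_squared`` is
    from an OLS of a on b.
    """
    a = np.asarray(platform_a, dtype=float)
    b = np.asarray(platform_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("platform readings must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise InsufficientDataError(f"need >= 2 pairs, got {n}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lower = bias - 1.96 * sd
    loa_upper = bias + 1.96 * sd
    grand_mean = float(((a + b) / 2.0).mean())
    percent_bias = 100.0 * bias / grand_mean if grand_mean != 0 else float("nan")

    tq = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    bias_ci = (bias - tq * se_bias, bias + tq * se_bias)
    var_loa = sd**2 * (1.0 / n + 1.96**2 / (2.0 * (n - 1)))
    se_loa = float(np.sqrt(var_loa))
    loa_ci_lower = (loa_lower - tq * se_loa, loa_lower + tq * se_loa)
    loa_ci_upper = (loa_upper - tq * se_loa, loa_upper + tq * se_loa)

    if np.ptp(b) == 0 or np.ptp(a) == 0:
        r2 = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
    else:
        r2 = float(stats.linregress(b, a).rvalue ** 2)

    return AgreementReport(
        n_pairs=n,
        bias=bias,
        percent_bias=percent_bias,
        sd_diff=sd,
        loa_lower=float(loa_lower),
        loa_upper=float(loa_upper),
        loa_width=float(loa_upper - loa_lower),
        bias_ci=(float(bias_ci[0]), float(bias_ci[1])),
        loa_ci_lower=(float(loa_ci_lower[0]), float(loa_ci_lower[1])),
        loa_ci_upper=(float(loa_ci_upper[0]), float(loa_ci_upper[1])),
        regression_r_squared=r2,
    )


def photobleaching_delta(
    pre: list[WellMeasurement], post: list[WellMeasurement]
) -> list[BleachingDelta]:
    """Per-well pre/post-activation decrease of mean fluorescence.

    Measurements are matched by (well_id, channel); each matched pair must
    carry the numerically identical segmentation threshold (held constant
    across timepoints by design), otherwise the provenance check fails.
    Positive values mean a decrease.

    The media background level recorded with each measurement (from the
    cell-free background ROIs that also set the threshold) is subtracted
    before forming the ratio: media autofluorescence does not bleach, so
    leaving it in the denominator would dilute the fractional decrease of
    the drug-associated signal. It cancels in the absolute decrease. This
    mirrors the study design's use of cell-free wells for signal
    calculation; measurements constructed without a background level
    (default 0) reduce to the plain pre/post ratio.
    """
    post_by_key = {(m.well_id, m.channel): m for m in post}
    deltas = []
    for m_pre in pre:
        key = (m_pre.well_id, m_pre.channel)
        m_post = post_by_key.pop(key, None)
        if m_post is None:
            raise PairingError(f"no post-activation measurement for {key}")
        if m_post.threshold_used != m_pre.threshold_used:
            raise ProvenanceError(
                f"threshold mismatch for {key}: "
                f"pre {m_pre.threshold_used} vs post {m_post.threshold_used}"
            )
        if m_post.background_level != m_pre.background_level:
            raise ProvenanceError(
                f"background level mismatch for {key}: "
                f"pre {m_pre.background_level} vs post {m_post.background_level}"
            )
        bg = m_pre.background_level
        pre_sig = m_pre.mean_signal - bg
        post_sig = m_post.mean_signal - bg
        absolute = pre_sig - post_sig  # background cancels: equals raw pre - post
        fractional = absolute / pre_sig if pre_sig > 0 else float("nan")
        deltas.append(
            BleachingDelta(
                concentration=m_pre.concentration,
                pre_mean=pre_sig,
                post_mean=post_sig,
                absolute_decrease=absolute,
                fractional_decrease=fractional,
            )
        )
    if post_by_key:
        raise PairingError(f"unmatched post-activation measurements: {sorted(post_by_key)}")
    return sorted(deltas, key=lambda d: d.concentration)


def release_fraction(m: ReleaseMeasurement) -> float:
    """Percent drug release from the serum-stability fluorescence triplet.

    Evaluates ``(F_final - F_initial) / (F_X100 - F_initial) × 100`` exactly.
    Values outside [0, 100] are possible on noisy inputs and are returned
    as-is with a warning.
    """
    denom = m.f_triton - m.f_initial
    if denom == 0:
        raise UndefinedReleaseError("f_triton equals f_initial: release undefined")
    pct = 100.0 * (m.f_final - m.f_initial) / denom
    if not 0.0 <= pct <= 100.0:
        warnings.warn(
            f"release fraction {pct:.1f}% outside [0, 100]: noisy input?",
            stacklevel=2,
        )
    return float(pct)
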