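# Methods

## Problem and scope

`mesofluor` implements the quantitative image-processing chain for widefield
(mesoscopic) fluorescence imaging of multi-well tumor-spheroid cultures
treated with a light-activatable liposomal doxorubicin/porphyrin carrier.
The measurement problem is to turn raw camera frames — contaminated by dark
offset, excitation bleed-through, and well-plate reflections — into per-well
mean fluorescence values that are linear in the administered drug
concentration, and then into the derived readouts: a dose-response
calibration line, the pre/post-activation porphyrin photobleaching delta,
the serum-release fraction, and Bland–Altman agreement against a bulk
plate-reader. A synthetic image generator with planted ground truth drives
all verification: every stage is tested by recovering what was planted.

## Correction model

Each imaged (well, channel, timepoint) consists of a fluorescence frame `F`
and a reference frame `ND` acquired through a neutral-density filter whose
optical density matches the emission filter. Under matched excitation, the
ND frame sees (ideally) only the excitation light and its reflections.
After dark subtraction (pixelwise mean of the session's dark frames), the
leakage component of `F` is modelled as a linearly scaled version of `ND`.
The scale `α` is fitted by ordinary least squares through the origin over
water-filled calibration wells, where the true fluorophore signal is zero:

    α = Σ F·ND / Σ ND²          (pooled over all calibration pixels)

The closed form is the exact minimiser of Σ(F − α·ND)²; tests verify this
against a 1-D numerical minimisation. The fit quality is reported as the
uncentred R² (1 − Σ(F − αND)²/ΣF²), the standard convention for
through-origin regression; per-well α values are recorded to report the
session mean ± SD. Correction then subtracts a spatially weighted estimate:

    F_corr = F − α · ND · M,    M = clip(smooth(ND)/max(smooth(ND)), 0, 1)

with `smooth` a Gaussian blur (default SD 2 px; 0 disables it). The mask is
continuous, 1 at the brightest leakage location, and prevents
overcorrection where leakage is negligible. A consequence worth noting:
where `M < 1`, a fraction of the true leakage survives correction. Because
the illumination pattern is common to all wells of a session, this residual
is an additive constant across wells — it moves the intercept of the
dose-response fit, never the slope. Negative corrected intensities are kept
(clipping before averaging would bias low-signal wells upward) and floored
only at segmentation.

## Segmentation and quantification

A pixel belongs to drug-bearing cellular structure if its corrected
intensity strictly exceeds mean + k·SD (default k = 3, sample SD) of
cell-free media background, pooled over background ROIs outside the
cluster boundaries (fallback: the four corner squares of the well's
analysable region). Segmentation is restricted to the central well region
(frame inset by 20% of its side) so rim reflections are never counted as
signal. Thresholds and background levels are estimated once per
(well, channel) — at the pre-activation timepoint when both exist — and
held numerically constant across timepoints; downstream pairing asserts
this provenance. The per-well readout is the arithmetic mean over
segmented pixels. Empty segmentations propagate as missing values (below
detection), never as zeros. With Gaussian-like noise, mean + 3 SD admits
~0.13% of background pixels; these false positives sit at threshold level
and dilute per-well means by roughly n_fp/n_cluster (~1% at the default
geometry). This is an inherent property of pure intensity thresholding; an
optional minimum-object-size filter removes it but is off by default, and
the dose-response recovery test budgets for it via its Monte-Carlo error.

## Statistics

- **Dose-response**: OLS with intercept of mean well signal on
  concentration; centred R²; constant responses report R² = 0. Fold change
  is the mean at the highest concentration over the lowest nonzero one.
- **Photobleaching**: per-well fractional decrease of the
  background-referenced mean, (pre − post)/(pre − bg). The media
  autofluorescence and any residual leakage do not bleach; they cancel in
  the absolute decrease but would dilute the plain ratio (a planted factor
  0.80 would read ~0.175 instead of 0.200 at the default conditions). The
  background level is the same cell-free ROI mean that sets the threshold —
  the study design's cell-free control/blank wells exist precisely to
  support this referencing.
- **Release fraction**: (F_final − F_initial)/(F_X-100 − F_initial) × 100%,
  evaluated exactly; out-of-range values are returned with a warning.
- **Agreement**: differences d = A − B of paired platform readings;
  bias = mean(d), 95% limits of agreement bias ± 1.96·sample SD(d); bias CI
  from the t distribution (n is small, typically 4 concentration-group
  means); LoA CIs from the standard approximate variance
  sd²(1/n + 1.96²/(2(n−1))); percent bias normalised by the grand mean of
  pairwise means; regression R² from OLS of A on B.
- **Resolution arithmetic**: USAF-1951 frequency 2^(group + (element−1)/6)
  lp/mm; single-bar line width 500/frequency μm; display rounding half-up
  to 2 decimals, full precision internally.

## Synthetic generator: what it emulates, and what not

Wells are rendered as individual 128×128 camera crops (a well-sized cutout
of the EMCCD field). Spheroid clusters are hemispherical caps; widefield
imaging integrates emission along the optical path, so per-pixel emission
is uptake coefficient × concentration × local cap thickness; overlapping
caps add. Two archetypes capture the observed morphological contrast:
`compact` (4–8 caps, radius 7 ± 1.5 px, dense central packing —
SCC-like) and `dispersed` (8–16 caps, radius 4.5 ± 2 px, looser packing,
flatter profile — SKOV-3-like); over repeated seeds the dispersed
component-size CV exceeds the compact one. Media contributes a uniform
background of 9.5 emission units ≈ 3% of the 9 μg/mL peak cluster signal,
the magnitude regime reported for media background in this assay.

The camera model: counts = dark (100) + vignetting × (gain (100/emission
unit) × emission + g × leakage pattern) for the fluorescence role;
dark + vignetting × leakage for the ND role; dark alone for dark frames.
The planted bleed-through fraction g defaults to 0.91, the reported
session-mean scaling. The leakage pattern is a 500-count in-well base plus
1500-count arcs on a ring near the frame edge (plastic-rim reflections).
Noise is Poisson shot noise on the expectation plus Gaussian read noise
(SD 5 counts) — the usual EMCCD approximation — with an optional relative
Gaussian term (2%) used for calibration-recovery studies. All randomness
flows through explicit seeds; identical seeds are bit-for-bit reproducible.

The default experiment plants one treatment well per concentration
(1, 3, 6, 9 μg/mL), a drug-free control, a cell-free drug-only blank, a
4-water-well calibration session per channel, and a porphyrin bleach
factor (default 0.9) applied to post-activation emission. An uptake
coefficient of 5 emission units per (μg/mL · px of thickness) puts the
9 μg/mL wells near (but almost never beyond) the 16-bit range, matching
how exposure is chosen in practice.

Not emulated: photon transport in scattering tissue (no radiative
transfer), depth-dependent attenuation, spatial drug gradients within a
cluster beyond the thickness law, saturating uptake kinetics, plate-reader
physics beyond a planted multiplicative bias. Passing recovery tests
therefore demonstrates correctness of the processing chain under the
stated acquisition model, not robustness to optical effects the generator
does not contain.

## Verification design and problem sizes

Exactness checks run noiseless: a uniform leakage pattern makes M ≡ 1, so
a zero-fluorophore well corrects to exactly zero and quantified means are
exactly proportional to concentration (with zero media offset and one
shared spheroid geometry across wells — geometry that varies per well
bounds even noiseless R² below 1, which is why the realistic default keeps
independent geometry and tests medians instead). Stochastic checks use
fixed seeds: leakage recovery (4 wells, 2% relative noise) lands within
±0.03 of the planted 0.91 with through-origin R² > 0.95; the 50-seed
end-to-end study yields median dose-response R² ≈ 0.975 and a replicate
mean of fitted slopes within 2 Monte-Carlo standard errors of the planted
expectation (the planted slope per seed is the OLS slope of the noiseless
expected well means computed from that seed's true thickness maps);
planted bleach factors 0.80/0.90/0.95 are recovered within ±0.02. The
suite sizes (128×128 wells, 50 seeds, 5-seed bleach studies) keep the full
run under ~20 s while leaving the Monte-Carlo margins comfortable.

## Known limitations

- The ND reference is modelled as leakage-only; real matched-OD filters
  pass a small fluorophore fraction (exposed as `nd_contamination`, default
  0, which biases α upward when nonzero).
- α is global per channel per session; spatial variation of the leakage
  ratio is handled only through the mask.
- The mean+3SD threshold's ~0.13% false-positive admission imposes a ~1%
  downward dilution of segmented means (see above).
- Whether through-origin fit quality should be reported with centred or
  uncentred totals is a convention choice; the uncentred form is used and
  stated wherever printed.
- Bright pixels of the 9 μg/mL compact wells occasionally reach the 16-bit
  ceiling when written to TIFF (in-memory analysis is unclipped); this is
  faithful to sensor saturation but slightly compresses the top of the
  dose-response line in disk-based runs.
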