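# mesofluor

Quantitative widefield fluorescence imaging of light-triggered liposomal
drug release in multi-well tumor-spheroid models.

Porphyrin-phospholipid (PoP) liposomes carry doxorubicin (Dox) and release
it on near-infrared illumination; both the carrier (PoP, ~720 nm emission)
and the payload (Dox, ~590 nm) are fluorescent, so a filtered widefield
imaging system can localise the carrier, trigger release, and read out the
delivered drug — if the images can be quantified. `mesofluor` implements
that quantification chain for well-plate spheroid assays:

1. **Calibration** — dark subtraction, then estimation of the excitation
   bleed-through scaling factor α by through-origin OLS over water-filled
   calibration wells, where the neutral-density (ND) reference frame sees
   only excitation light: `α = Σ F·ND / Σ ND²`.
2. **Correction** — masked leakage subtraction
   `F_corr = F − α·ND·M`, with `M` the max-normalised, lightly smoothed ND
   signal (a continuous weight in [0, 1] that prevents overcorrection).
3. **Segmentation** — pixels exceeding the cell-free media background mean
   plus 3 sample standard deviations, measured from ROIs outside the
   cluster boundaries; thresholds held constant across pre-/post-activation
   timepoints.
4. **Quantification** — per-well mean corrected fluorescence over segmented
   pixels only.
5. **Statistics** — linear dose-response calibration (OLS, centred R²),
   fold change, pre/post porphyrin photobleaching deltas, serum-release
   fraction `(F_final − F_initial)/(F_X-100 − F_initial) × 100%`, and
   Bland–Altman agreement (bias, 95% limits of agreement ±1.96 SD, CIs)
   against bulk plate-reader readings.
6. **Resolution bookkeeping** — USAF-1951 group/element arithmetic
   (`f = 2^(group+(element−1)/6)` lp/mm, line width `500/f` μm) and
   field-of-view areas.

A synthetic image generator (`mesofluor.simgen`) emulates the acquisition —
hemispherical-cap spheroids with thickness-proportional emission, compact
vs dispersed morphology archetypes, spatially structured rim-reflection
leakage, dark offset, Poisson + read noise — with full ground truth, so
every stage is verified by parameter recovery. See `docs/methods.md` for
the model and its assumptions.

## Worked example

Simulate the bundled 4-concentration experiment (1, 3, 6, 9 μg/mL, compact
spheroids, planted leakage fraction 0.91, planted bleach factor 0.9) and
run the pipeline:

```sh
python analysis/01_simulate.py
python analysis/02_calibrate.py
python analysis/03_quantify.py
```

which prints (abridged):

```
dox: alpha = 0.9082 (session 0.9082 ± 0.0002, R² = 0.9959, n = 4 wells)
pop: alpha = 0.9086 (session 0.9086 ± 0.0007, R² = 0.9959, n = 4 wells)
...
 W1  dox post_activation  1.0  ...   3660.9
 W2  dox post_activation  3.0  ...  11802.0
 W3  dox post_activation  6.0  ...  26733.1
 W4  dox post_activation  9.0  ...  28059.7
dox: slope 3218.7 A.U./(μg/mL), intercept 2275.0, R² = 0.9049
```

The recovered α sits within 0.002 of the planted 0.91. The per-well means
rise with concentration; this particular seed drew unusually thin clusters
into the 9 μg/mL well, so its single-plate R² is 0.90 — morphological
scatter between wells is the dominant noise source, and over 50 simulated
plates the median dose-response R² is 0.975 (`analysis/04_dose_response.py`):

```
recovery over 50 seeds: fitted 3288.3 ± 99.4 (SE) vs planted 3325.6; median R² 0.9755
```

`analysis/05_agreement_bleaching.py` adds the Bland–Altman comparison
against simulated plate-reader readings and the porphyrin bleaching
readout (planted factor 0.9 recovered as a mean fractional decrease of
0.101), and `analysis/06_resolution_table.py` prints the resolution table:

```
group 1 element 3: 2.52 lp/mm, line width 198.43 μm (FOV 5.1 × 5.1 cm = 26.01 cm²)
group 2 element 6: 7.13 lp/mm, line width 70.15 μm (FOV 3.2 × 3.2 cm = 10.24 cm²)
```

The same stages are available as a CLI for real or simulated acquisitions
(`mesofluor simulate|calibrate|correct|quantify|analyze|run|resolution`),
driven by a YAML plate configuration (`examples/demo_plate.yaml`).

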