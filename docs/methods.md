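# Methods

This note documents the models, numerical choices and limitations of
`uraman`. Empirical figures quoted here are the ones computed by the
test suite and `scripts/acceptance.py`; nothing is reported that the
code does not itself recompute.

## Pre-processing chain

The chain runs despike → baseline removal → water-band normalization,
in that order, followed by SNR-based exclusion.

**Despiking.** Cosmic rays hit one or two adjacent detector channels.
A channel is flagged when its deviation from the 5-channel running
median exceeds `despike_z` (default 8) robust standard deviations.
The robust scale is estimated from first differences of the spectrum,
`1.4826 · MAD(diff(y)) / √2`: the first difference cancels smooth
trends, and the MAD is insensitive to the spikes themselves. (A MAD
taken on the running-median residual is unusable here: in
slope-dominated regions the 5-point window is locally monotone, its
median equals the center sample, and the residual collapses to exactly
zero on roughly half the channels.) Flagged channels are replaced by
linear interpolation between flanking unflagged channels, and the count
is recorded in the spectrum metadata. If more than 20% of channels are
flagged the routine refuses — that pattern is signal, not artifact.
Side effect worth knowing: with the default z = 8, the very tops of
extremely tall narrow bands (e.g. heavily glycosuric samples) can be
flagged and flattened by one channel; this behaves like mild detector
saturation and has no measurable effect on calibration (held-out
glucose r ≥ 0.99 in the recovery tests).

**Fluorescence baseline.** A polynomial of order 5 (configurable) is
least-squares fitted on a conditioned domain (the axis mapped to
[−1, 1]); after each fit, intensities above the fit are clipped to the
fit and the fit is repeated, so peaks — which lie above the smooth
background — are progressively excluded. Iteration stops when the fit
changes by less than `baseline_tol` (default 1e-6) in relative norm, or
at `baseline_max_iter` (default 100), in which case a non-convergence
flag is set on the metadata rather than raising. The decomposition is
exactly additive: corrected + baseline reproduces the input to 1e-9.
On a pure 5th-order polynomial the residual is numerically zero; a
polynomial plus a 1000-count Lorentzian (FWHM 12 cm⁻¹) is recovered
within 5% of the true peak height.

**Water-band normalization.** Every intensity is divided by the
trapezoidal integral of the baseline-corrected spectrum over
1610–1710 cm⁻¹ (center 1660, half-width 50). The band *area* reading
was chosen over peak height: an integral is robust to channel noise,
and the 100 cm⁻¹ window covers the broad water/amide envelope without
reaching the quiet region above 1750. Normalization is idempotent and
scale-invariant, and the post-normalization band area is 1 to 1e-9.

**SNR and quality control.** SNR is defined as the maximum
baseline-corrected intensity in 950–1050 cm⁻¹ (the dominant urea band
region, the strongest feature of urine spectra) divided by the standard
deviation of the linearly detrended intensity in 1750–1800 cm⁻¹ (free
of analyte bands). A zero noise SD returns +inf. Spectra with
SNR < 10 are excluded; excluding every spectrum is an error.

## Chemometric models

All models are implemented directly on numpy; scikit-learn appears only
as an independent cross-check in the tests.

**PCA** is computed by SVD of the column-centered spectral matrix.
Loadings are unit-norm component directions over wavenumbers
(spectrum-shaped); scores are per-spectrum projections. Note that some
spectroscopy literature swaps this nomenclature (calling the
spectrum-shaped vectors "Scores"); this package uses the conventional
meaning throughout. Explained-variance ratios match an independent
eigendecomposition of the sample covariance to 1e-8, and full
reconstruction is lossless to 1e-6.

**PLS1 (NIPALS).** X and y are mean-centered, never variance-scaled —
all channels share the same arbitrary intensity units, and scaling
would inflate noise channels. Each component takes the weight vector
`w ∝ Xᵀy` on the current residuals, scores `t = Xw`, loadings
`p = Xᵀt/tᵀt`, `q = yᵀt/tᵀt`, and deflates `X ← X − t pᵀ`. The
collapsed regression vector is `b = W (PᵀW)⁻¹ q`. At full rank the
solution coincides with least squares (verified against the
minimum-norm `lstsq` solution to 1e-6), and predictions agree with an
independent PLS implementation to 1e-6.

**Leave-one-out cross-validation.** Two hold-out units are supported:
`spectrum` (one row at a time) and `sample` (all replicate spectra of a
sample leave together, the default — replicates of one sample are
pseudo-replicates, and splitting them across training and test leaks
sample identity). Centering and deflation are recomputed inside every
fold; a leakage test verifies that corrupting a held-out response
cannot change that unit's own prediction. One NIPALS pass at `max_lv`
per fold yields predictions for every smaller component count. RMSEcv
and Pearson r are computed over held-out predictions per LV count, and
the model order is the argmin of RMSEcv with ties broken toward fewer
components. `max_lv` defaults to 10.

**PLS-DA** regresses the class code (CT = 1, DM&HBP = 2) on spectra and
thresholds predictions at the midpoint 1.5; a score of exactly 1.5 is
assigned to DM&HBP (deterministic, documented tie rule). The default
model order is 7 latent variables.

**LDA** uses class means, a pooled within-class covariance with a small
ridge (λ = 1e-6 × mean diagonal) for numerical stability, and empirical
priors. Classification maximizes the linear discriminant score; the
boundary matches the closed-form two-class discriminant.

**Group testing on components.** Each PCA component's scores are
compared between groups with a pooled-variance two-tailed Student's
t-test (α = 0.05), preceded by a Kolmogorov–Smirnov normality screen
per group (α = 0.1) run as `scipy.stats.kstest` against a normal with
the sample mean and SD — no Lilliefors small-sample correction is
applied, and when normality is rejected the t-test is still reported
with the non-normality annotated rather than switching to a
nonparametric test.

**Evaluation conventions.** DM&HBP is the positive class: sensitivity
is the detected fraction of DM&HBP units, specificity of controls.
Report percentages are rounded half-up to one decimal; raw fractions
are retained internally. Unit conversion uses
mg/dL = mmol/L × M / 10 with M = 60.06 (urea), 113.12 (creatinine),
180.16 (glucose) g/mol; phosphate (assayed as mixed species) and total
protein have no single molar mass and are not convertible.
Reference-range flagging is strictly greater-than the upper bound; a
value exactly at the bound is not flagged, and unknown sex falls back
to the wider of the men's/women's bounds.

## Synthetic cohort generator

The generator emulates the study design: 20 samples per group, 6
replicate spectra per sample (240 spectra), on a 400–1800 cm⁻¹ grid at
2 cm⁻¹ (701 channels). One seeded `numpy` generator drives every draw
in a fixed order (per group, per sample: the biomarker panel, the
latent component levels, then each replicate's baseline scale, noise
and spikes), so identical configurations are bit-identical.

**Concentrations.** Truncated-at-zero normals with the published group
means/SDs for urea, creatinine, phosphate, total protein, and control
glucose (0.23 ± 0.04 mmol/L). DM&HBP glucose is a 75/25 mixture —
normal(0.3, 0.1) truncated at 0, and a lognormal with natural-scale
mean 68 and SD 50 mmol/L — the minimal model that reproduces both the
group's heavy-tailed moments (≈17 ± 39 mmol/L) and a ≈25%
above-reference (0.83 mmol/L) fraction. Verified at 10,000 draws.

**Spectra.** A linear Beer–Lambert-style mixture: unit-height
component spectra (Lorentzian FWHM 12 cm⁻¹ for the small metabolites,
Gaussian FWHM 40 cm⁻¹ protein bands; positions from the urine Raman
literature, with the deliberate overlaps at 516, 910 and 1080 cm⁻¹)
scaled by concentration and per-analyte response coefficients, plus a
Gaussian water band at 1660 cm⁻¹, a fixed-shape 5th-order-polynomial
fluorescence baseline with a per-spectrum random scale (U(0.5, 1.5) ×
300 counts), iid Gaussian noise, and Poisson(0.2) single-channel
cosmic-ray spikes of 20–100× the noise SD.

**Response scales.** True Raman cross-sections of the five analytes
are not published, so the coefficients (urea 0.5, creatinine 4,
glucose 6, phosphate 3, protein 7 counts per concentration unit;
noise SD 1.5 counts) were set once by variance budgeting: band heights
of tens to ~150 counts keep every analyte band below the despiking
threshold while giving the structured (concentration-driven) variance a
large margin over the white-noise floor, so that six principal
components capture > 98% of spectral variance and held-out glucose
calibration reaches r ≥ 0.99 on a default cohort — numbers that mirror
the qualitative behavior reported for real urine cohorts, not fits to
them.

**The latent metabolic-profile component.** Real urine contains many
metabolites beyond the five assayed biomarkers, and exploratory PCA on
real cohorts attributes several discriminating components to unassayed
protein/amino-acid features. The generator therefore includes one
aggregate "metabolic profile" component (seven narrow bands at
622–1635 cm⁻¹) whose level is group-dependent (CT 1.0 ± 0.33 vs DM&HBP
2.0 ± 0.33 arbitrary units, 30 counts per unit). This is what makes
full-spectrum PLS-DA genuinely outperform LDA on the five assayed
concentrations — without it the spectra would be a noisy function of
the LDA features and the observed dominance of spectral classification
would be information-theoretically impossible to emulate.
`synthesize_spectrum` adds latent components only when levels are
passed explicitly (as `generate_cohort` does), so the single-spectrum
forward model remains the exact five-analyte linear mixture.

**What the simulator does not model**, and hence what passing tests do
not show about real data: instrument response and wavelength-dependent
collection efficiency, photobleaching kinetics, pH- and
ionic-strength-dependent band shifts, matrix effects and
analyte-analyte spectral interactions, non-Gaussian detector noise,
and any real biological covariance between analytes (draws are
independent across analytes). Recovery targets are therefore stated
against simulator truth, not against clinical performance.

## Pipeline

`run_pipeline` executes simulate/load → preprocess+QC → PCA (6
components, group t-tests) → per-analyte LOOCV-PLS calibration → three
classification blocks, and is deterministic given the seed. The
LDA-on-PLS-predictions block consumes the *cross-validated* per-spectrum
predictions at each analyte's chosen LV, never training fits, and all
classifier evaluation is leave-one-sample-out. Intermediates
(preprocessed matrix, QC table, selection curves, held-out predictions,
report) are persisted as delimited text when an output directory is
set, with per-stage log records (stage, parameters, counts in/out) on
the report.

**Chance-level check.** With the group difference disabled (both groups
drawn from the control distributions, including the latent component),
the three classifiers' held-out accuracies average to chance. The check
is formulated on the *mean* accuracy per classifier across 10 seeded
cohorts (required to lie in [0.35, 0.65]): with only 40 hold-out units
per cohort, single-seed accuracies have a binomial SD of ≈0.08 around a
LOO-deflated mean slightly below 0.5 (the well-known anti-learning bias
of leave-one-out on null data), so individual seeds can legitimately
stray outside any narrow band while the mean is stable (observed means
≈0.43–0.46 per classifier).

## Numerical conventions and degenerate inputs

- Axes must be strictly increasing, within 100–4000 cm⁻¹, length ≥ 16;
  operations on spectra collections reject mixed axes.
- Resampling is linear interpolation, exact on affine profiles, and
  refuses to extrapolate.
- PLS refuses a zero-variance response and degenerate (uncorrelated)
  components; LOOCV requires ≥ 3 hold-out units; LDA requires ≥ 2 units
  per class.
- Text serialization keeps 12 significant digits; round-trips preserve
  metadata exactly and intensities to 1e-9 relative.
- The default problem sizes (240-spectrum cohorts, 10 LV maximum,
  10-seed null studies) keep a full test-suite run at a few minutes on
  one CPU.

## Known limitations

- The SNR definition and the water-band integration limits are
  reasonable choices, not published constants; results are insensitive
  to the exact window edges but the absolute SNR scale depends on them.
- The despiking flag rule can shave one channel from extremely tall
  narrow bands (see above).
- Only two-class discrimination is implemented; no multiple-testing
  correction is applied across PCA components (matching common practice
  in the field's exploratory analyses).
- The latent metabolic-profile effect size is a free parameter of the
  simulator; the classification accuracies on synthetic cohorts should
  be read as demonstrations of correct model mechanics, not as clinical
  performance estimates.
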