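# Methods

## Acquisition model

The pipeline emulates a 3 T abdominal DCE-MRI protocol: a pre-contrast
variable-flip-angle (VFA) T1-mapping acquisition with spoiled
gradient-echo (SPGR) readout at flip angles 3°, 6°, 9°, 12° and 15°
(TR = 2.8 ms), followed by a dynamic series at 12° with 44 frames at a
uniform 6-s resolution (4.4 min total). The contrast bolus is administered
at the start of the third frame, so two frames form the pre-contrast
baseline. Acquisition constants live in `AcquisitionMeta`; every physical
constant the analysis depends on (relaxivity, input-function constants,
exclusion thresholds, bin count, fit bounds) is a configuration value and
is recorded in the run manifest.

The protocol's real-world breath-hold/free-breathing alternation is *not*
modelled as timing gaps; sampling is uniform at 6 s. The scanner's true
per-frame timetable under alternating breathing is ambiguous, and a single
stated temporal resolution is the defensible reading.

## T1 mapping

Per pixel, (m0, T1) minimise the squared residual of the SPGR equation
over the flip angles. A closed-form linearisation (regression of S/sin θ
on S/tan θ; the slope is E = e^(−TR/T1)) initialises a bounded nonlinear
least-squares refinement with T1 ∈ [0.05, 10] s — wide enough for any
tissue at 3 T. Pure linearisation is biased at low SNR, which motivates
the second stage; on noiseless data the two agree to well under 0.5%.
Degenerate pixels (zero signal, or signal constant across angles, where no
unique solution exists) are flagged as failures and propagate as NaN —
never silently zeroed.

## Concentration

m0 is contrast-independent, so it is taken from the VFA fit and not
re-estimated per frame. Each dynamic frame is inverted for T1(t)
analytically (the SPGR equation is monotone in T1 below saturation), and

C_t(t) = (1/T1(t) − 1/T1_ref) / r,

where 1/T1_ref comes from inverting the averaged pre-bolus frames, making
the baseline concentration exactly zero. Signals outside the attainable
range (0, m0 sin θ) are flagged per pixel and counted. The default
relaxivity is r = 3.9 s⁻¹mM⁻¹ (gadodiamide at 3 T); it is always an
explicit configuration value because reported parameter values scale
inversely with the r assumed.

## Input function and kinetic model

The plasma input is the bi-exponential population curve
C_p = D(a₁e^{−m₁τ} + a₂e^{−m₂τ}) with D = 1.0 mmol/kg, a₁ = 2.4 kg/l,
a₂ = 0.62 kg/l, m₁ = 3.0 min⁻¹, m₂ = 0.016 min⁻¹, zero before bolus
arrival. The rates are per-minute (the standard convention for this
curve); time is converted to minutes before exponentiation so K^trans and
k_ep are reported in min⁻¹. Note D = 1.0 mmol/kg is the literature
normalisation of this curve even though clinical dosing is typically
0.1 mmol/kg; both are configuration fields and the discrepancy is
deliberately not "corrected" — downstream parameters scale linearly with
D, so changing it rescales K^trans and v_p uniformly.

The extended Tofts convolution with a bi-exponential input has a closed
form; each exponential contributes
K^trans·D·aᵢ·(e^{−k_ep s} − e^{−mᵢ s})/(mᵢ − k_ep). When |mᵢ − k_ep| <
1e−8 the L'Hôpital limit K^trans·D·aᵢ·s·e^{−k_ep s} is used for numerical
stability. The closed form is verified against adaptive quadrature of the
convolution integral to 1e−6 relative, including the degenerate rates.

Voxelwise fitting is bounded nonlinear least squares over
K^trans ∈ [0, 5] min⁻¹, v_e ∈ [1e−3, 1], v_p ∈ [0, 0.5] — a physiologic
envelope intentionally wider than the histogram module's exclusion
thresholds, so pixel exclusion remains a distinct, testable step. The
deterministic start (0.1, 0.3, 0.02) gets one fallback restart; k_ep is
reported as K^trans/v_e by definition. Non-converged pixels are flagged
and counted. An all-zero curve is a legitimate non-enhancing voxel
(K^trans ≈ 0, v_p ≈ 0), not a failure.

## Histogram metrics

Pixels with K^trans outside [0, 1.2] min⁻¹ (values above 1.2 reflect
pseudo-permeability in vessels or fit errors) or v_e outside [0, 1] are
excluded; retention is the closed interval, since "larger than" excludes
strictly greater values. Mean, Skewness and Kurtosis are computed from the
raw retained values with population moment estimators (skew = m₃/m₂^1.5,
kurtosis = m₄/m₂² − 3), so a normal distribution scores 0 for both — the
excess convention. Mode is the centre of the most-populated bin of a fixed
50-bin histogram over the threshold range (bin widths 0.024 min⁻¹ for
K^trans and 0.02 for v_e), lowest bin on ties. Whether skewness/kurtosis
are computed from raw or binned values is a declared convention of this
package (raw), chosen so the mean is independent of binning; zero-variance
inputs have undefined shape metrics and are flagged rather than reported
as 0.

## Reproducibility statistics

Measurements are long-format records (subject, rater, scan, replicate,
metric, value). Three designs: intra-observer (2 replicates by rater 1),
inter-observer (3 raters), scan–rescan (2 scans read by rater 1).

- **ICC**: two-way random-effects, absolute-agreement, single-measure
  ICC(A,1) from the two-way ANOVA mean squares, with the McGraw–Wong
  F-distribution 95% CI (Satterthwaite df) and the banding good (> 0.75) /
  moderate (0.5–0.75) / poor (< 0.5). This variant is applied uniformly to
  all three designs; it is the standard choice for agreement when the ICC
  flavour is otherwise unspecified. The implementation is cross-checked
  against `pingouin.intraclass_corr` in the tests.
- **CoV**: per subject, sd of the repeat values over the absolute mean,
  ×100, then averaged over subjects — the per-subject-then-average
  construction is applied to all three designs for uniformity (a pooled
  alternative is available behind a flag). The absolute mean keeps CoV
  positive for metrics whose mean is negative (excess kurtosis routinely
  is); the convention is recorded in the result metadata. Zero-mean
  subjects are excluded and counted.
- **Difference tests**: two-sided paired t (intra, rescan) and one-way
  ANOVA across raters (inter), α = 0.05, no multiple-testing correction.
  Zero-variance differences leave the t statistic undefined and flagged.
- **Sample size**: Walter–Eliasziw–Donner approximation
  n = 1 + 2k(z₁₋α + z₁₋β)²/[(k−1)(ln C₀)²],
  C₀ = (1 + kρ₀/(1−ρ₀))/(1 + kρ₁/(1−ρ₁)), ceiling-rounded, one-sided α by
  default (the standard formulation of the reliability hypothesis
  H₀: ρ = ρ₀ vs ρ > ρ₀; two-sided available). For ρ₀ = 0.75, ρ₁ = 0.9,
  k = 3, α = 0.05, β = 0.20 this yields n = 19.

## Synthetic studies

`make_phantom` draws smoothed correlated Gaussian fields (tunable
correlation length, default 4 px) min–max rescaled into per-parameter
ranges — defaults K^trans ∈ [0.1, 0.6] min⁻¹, v_e ∈ [0.3, 0.75],
v_p ∈ [0.01, 0.06], T1₀ ∈ [1.2, 1.6] s — inside a disc ROI, with
near-zero K^trans background. These ranges put the ROI means near the
0.3–0.4 min⁻¹ / ~0.5 regime typical of clear-cell renal tumours and
produce the skewed, non-normal histograms that make histogram metrics
interesting.

`simulate_series` composes the Tofts forward model, the relaxivity model
and the SPGR equation; noise is Rician by default (magnitude MR data:
magnitude of the signal plus complex Gaussian noise), Gaussian available
for linear-regime tests. At SNR ≳ 10 Rician noise behaves like Gaussian
(the noisy baseline mean stays within 2% of truth at σ = baseline/20),
which the tests verify.

Observer variation is emulated by perturbing the signed distance to the
ROI boundary with a smooth random field scaled to ±magnitude pixels, so
only a boundary band can change — the simplest model with manual
outlining's key property of touching only edge pixels. Scan–rescan
variation re-simulates the acquisition with fresh noise plus a small
multiplicative jitter (default sd 3%) of the true parameter fields,
standing in for biological/positioning drift between visits; there is no
published quantitative magnitude for either source, so these defaults are
single, fixed choices of plausible size.

`make_cohort` draws from a two-way random-effects model
y = μ + subject + rater + residual with configurable variances; the
implied absolute-agreement population ICC,
σ²_subject/(σ²_subject + σ²_rater + σ²_residual), is recorded with the
table, enabling parameter-recovery tests of the ICC estimator.

What the generator does **not** emulate: k-space/reconstruction effects,
motion and registration artifacts, B1 inhomogeneity, water exchange,
T2* effects, 3-D anatomy, or individually measured input functions.
Passing tests therefore demonstrate the correctness and calibration of the
analysis chain under the stated model, not robustness to those real-data
effects.

## Problem sizes and numerical choices

Pipeline identity checks run on 16×16–32×32 grids (hundreds of ROI
pixels), Monte-Carlo recovery on 200 voxels at SNR 20, ICC recovery on
50 seeded 200-subject cohorts, and test calibration on 2000 seeded null
replicates at the study's dimensions (21 subjects, 3 raters) — sizes at
which the sampling error of each check is comfortably below its pass
band. All generators take explicit seeds; identical configurations
reproduce outputs bit-identically, and each run directory's manifest
records the configuration hash and package versions.

## Known limitations

- The voxel fit is independent per pixel: no spatial regularisation, no
  per-voxel bolus-arrival estimation, no model selection against the
  plain Tofts model.
- ICC confidence intervals assume the balanced complete two-way layout;
  incomplete tables are rejected with the missing cells listed rather
  than analysed.
- The CoV of a metric whose subject means straddle zero (possible for
  skewness) is unstable by construction; the per-subject |mean|
  denominator bounds but does not remove this.
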