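# dcerepro

Quantitative DCE-MRI estimates tumour microvascular function by fitting a
pharmacokinetic model to the tissue response to a contrast-agent bolus.
Before such parameters — and especially histogram metrics of their
within-tumour distribution — can serve as imaging biomarkers, their
reproducibility across repeat readings, observers and repeat scans has to
be established. `dcerepro` implements the complete analysis chain needed
to do that, and a synthetic study generator so every stage can be validated
against known ground truth without patient data. It is aimed at imaging
scientists who develop or audit DCE-MRI perfusion pipelines.

## What it computes

**T1 mapping (VFA/SPGR).** Pre-contrast T1 and equilibrium signal m0 per
pixel from multi-flip-angle spoiled gradient-echo signals,

S(θ) = m0 · sin θ · (1 − E)/(1 − E cos θ), E = exp(−TR/T1),

by linearised initialisation plus bounded nonlinear least squares.

**Concentration.** Each dynamic frame is inverted through the SPGR
equation and converted with the relaxivity model
C_t(t) = (1/T1(t) − 1/T1₀)/r.

**Extended Tofts model.** C_t(t) = v_p·C_p(t) + K^trans · ∫₀ᵗ C_p(u)
e^{−k_ep(t−u)} du with k_ep = K^trans/v_e, driven by the bi-exponential
population input function C_p(τ) = D(a₁e^{−m₁τ} + a₂e^{−m₂τ})
(D = 1.0 mmol/kg, a₁ = 2.4 kg/l, a₂ = 0.62 kg/l, m₁ = 3.0 /min,
m₂ = 0.016 /min). The convolution is evaluated in closed form and fitted
per pixel with bounded least squares.

**Histogram metrics.** Pixels with K^trans outside [0, 1.2] min⁻¹ or v_e
outside [0, 1] are excluded; Mean, Mode, Skewness and excess Kurtosis are
computed with a fixed 50-bin histogram (bin widths 0.024 min⁻¹ and 0.02).

**Reproducibility statistics.** Paired t tests, one-way ANOVA, the
two-way random-effects absolute-agreement single-measure ICC(A,1) with
F-based 95% CI and good/moderate/poor banding (>0.75 / 0.5–0.75 / <0.5),
three coefficient-of-variation designs (intra-observer, inter-observer,
scan–rescan), and Walter–Eliasziw–Donner sample-size planning for ICC
reliability studies.

**Synthetic studies.** Spatially correlated phantoms, forward simulation
of the full acquisition with Rician noise, boundary perturbation of ROI
masks emulating observer outlining, and random-effects cohorts with known
population ICC.

## Worked example

`examples/04_phantom_pipeline.py` simulates a noiseless 24×24 phantom and
runs the full chain:

```
Ktrans: ROI mean = 0.4213, max relative error = 1.42e-12
ve    : ROI mean = 0.5684, max relative error = 6.88e-13
vp    : ROI mean = 0.0352, max relative error = 7.11e-12
converged: 256/256 pixels
```

The chain inverts itself to numerical precision: the fitted maps equal the
generating maps. `examples/06_reproducibility.py` draws a 21-subject,
3-rater cohort with population ICC 0.882 and prints

```
estimated ICC(A,1) = 0.847 (95% CI 0.696-0.931), good agreement, p = 2.27e-15
inter-observer CoV = 9.70%
ANOVA across raters: F = 0.733, p = 0.485
```

i.e. the agreement estimate recovers the population value, lands in the
"good" band, and the non-significant ANOVA shows no systematic rater
offset. The other examples cover sample-size planning, the input function,
T1 mapping and histogram metrics; each prints a line or two explaining its
numbers.

A thin CLI mirrors the library (`dcerepro simulate|t1fit|conc|fit|
histogram|repro|samplesize|demo`); `dcerepro demo --out runs/demo` writes a
complete run directory with NIfTI maps, the long-format measurement table,
the ICC/CoV results table, and a manifest for bit-identical re-runs.

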