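# Methods

## The measurement problem

Droplet digital PCR (ddPCR) partitions a reaction into ~10⁴–10⁵
water-in-oil droplets, each an independent endpoint PCR. When a target
sequence is rare — e.g. T-cell receptor excision circles (TRECs), an
episomal DNA marker of thymic output present at 10⁻³–10⁻⁴ copies per
cell in memory T-cell subsets — absolute quantification hinges on three
things this package implements: (i) the Poisson partition model that
converts the fraction of negative droplets into a concentration, (ii)
the bookkeeping around it (blank-derived thresholds, droplet QC,
replicate merging, a measured rather than assumed droplet volume) and
(iii) the validation statistics that say how far down the assay can be
trusted (LOB, LOD, LOQ, repeatability, hit rates). A second channel
carries a diploid reference gene (RPP30) whose concentration counts
genome equivalents, so target abundance can be put on a per-cell scale.

## Poisson quantification

With target copies loaded independently into droplets of volume V (µL)
at concentration c (copies/µL), the copies in one droplet are
Poisson(cV). The probability a droplet is negative is e^(−λ) with
λ = cV, so

    λ̂ = −ln(N_neg / N),        ĉ = λ̂ / V_droplet,

where N is the accepted droplet count and N_neg the negatives on the
channel. The delta method on the binomial negative fraction
p = N_neg/N gives SE(λ̂) = √((1−p)/(N·p)); 95% CIs are λ̂ ± 1.96·SE,
scaled by 1/V and floored at zero. Two boundary cases are handled
explicitly rather than clipped: a saturated well (N_neg = 0) raises a
`SaturationError` — λ is above the dynamic range, not a number — and an
all-negative well returns ĉ = 0 with a one-sided upper bound from the
rule of three (λ < 3/N).

`V_droplet` defaults to **0.70 nL**, the monolayer-microscopy value,
not the 0.85 nL assumed by the instrument software; concentrations
scale exactly as the inverse volume ratio, so this choice raises
reported concentrations by 0.85/0.70 ≈ 1.21× relative to the vendor
default. The nL→µL conversion happens in exactly one place
(`to_concentration`).

Per-cell quantities use the reference channel:
cells/reaction = c_ref·V_reaction/k with k = 2 reference copies per
diploid genome (configurable; the factor is a modelling choice, as
single-copy-per-haploid loci imply), and targets/cell =
c_target/(c_ref/k). The reaction volume defaults to 20 µL (the volume
loaded into the droplet generator from the 22 µL prepared mix; 22 is
the documented alternative). The ratio CI propagates only the target
channel by default: the reference is typically 10³–10⁴-fold more
abundant, so its relative SE is negligible; a full delta-method ratio
CI is available behind `propagate_ref_uncertainty=True`.

## Classification

Thresholds come from blank reactions (no-template controls and
target-negative cell-lysate controls): per channel, pooled-blank mean +
k·SD with **k = 7** by default. The choice of 7 is deliberate: blank
amplitude spread is approximately Gaussian, so k = 7 puts the
per-droplet false-positive probability near 10⁻¹², which keeps the
limit of blank at zero across dozens of 20,000-droplet wells while
remaining many SDs below the positive cluster. Manual practice sets
this line by eye from 3–8 blank wells; the rule makes that auditable
and repeatable. Degenerate blanks (zero SD) fall back to mean + a fixed
margin with a logged warning.

Ties go to negative (strict `>`), conservative for rare targets.
Exclusion regions are axis-aligned amplitude rectangles supplied in
configuration — a replayable record of manual gating of artifact
clusters — not automatic outlier detection; excluded droplets leave
`n_total` and are reported separately, and droplet QC (keep wells with
**more than 10,000** accepted droplets, strictly) applies after
exclusion. Replicate wells of one sample are merged by summing quadrant
counts before estimation; because λ̂ depends only on (N_neg, N), this
is exactly equivalent to concatenating the droplet tables, and it is
how a rare-target sample split over four reactions becomes one ~80,000
partition measurement.

## Validation statistics

* LOB = mean + 1.645·SD of blank-reaction concentrations (sample SD).
* LOD = LOB + 1.645·SD of the lowest dilution level.
* LOQ = the lowest tested level with CV ≤ 35% (inclusive); if an
  intermediate level fails but a lower one passes, the lower one is
  still the LOQ. When no level qualifies the result is an explicit
  "not reached", never a silent extrapolation. The replicate scale for
  the CV is configurable (targets/cell or copies/reaction) because both
  conventions appear in practice; both are supported and labelled.
* Repeatability: per-sample CV with the n−1 SD, plus the unweighted
  mean CV across samples. The n−1 convention is not cosmetic — it is
  what reproduces published triplicate tables digit-for-digit.
* Hit rate: a level's detection fraction, where a "detection" is ≥ 1
  positive target droplet in the merged group after exclusions (the
  natural digital-PCR call; with clean blanks at k = 7 a single droplet
  is meaningful). A probit model Φ(a + b·log₁₀c) is fitted by binomial
  maximum likelihood when rates vary; when every level is all-hit or
  all-miss the slope is unidentifiable and the fit is reported as
  "degenerate" rather than forced.

## Method comparison

Accuracy against a reference assay uses OLS of test on reference with a
t-based 95% CI on the slope and an explicit contains-1 flag (CI
inclusion, not a p-value, is the decision rule); monotone agreement
uses Spearman's ρ with mid-ranks; absolute agreement uses Bland-Altman
bias and 1.96·SD limits of agreement. The difference direction is a
labelled parameter (default test − reference) and is carried into the
output, because a bias sign with an unstated direction is
uninterpretable.

## Droplet volume from micrographs

A monolayer droplet appears as a bright disc whose equatorial
cross-section is in view, so area → equivalent diameter
d = 2√(A/π) → sphere volume V = (π/6)d³ (1 nL = 10⁶ µm³). Segmentation
is a global Otsu threshold (fixed threshold available), hole filling,
connected components, then an area filter — defaulting to
(0.25×, 2×) the median component area, which drops debris and merged
doublets without an absolute scale — and a circularity filter
(4πA/P² ≥ 0.8; digitized perimeters can push the ratio slightly above
1, so it is capped). Touching droplets are rejected, not watershed-split:
monolayer images have spacing, and a mis-split biases volume low.
The summary is mean, sample SD and a normal-approximation CI of the
mean (±1.96·SD/√n); with n ≈ 300 droplets the CI half-width at
SD 0.037 nL is ±0.0042 nL.

## The synthetic-data generator

The generator emulates the assay the analysis expects, with known
ground truth per droplet:

* Droplet count ~ round(Normal(20,000, 1,000)); volume per droplet
  truncated-Normal(0.70, 0.022) nL (>0), the crude-lysate volume
  spread.
* Copy loading: k ~ Poisson(c·Vᵢ) independently per droplet and per
  channel. Independence across channels is the modelled effect of
  restriction digestion of the template (no linked co-encapsulation);
  Poisson-per-droplet rather than multinomial allocation of a fixed
  pool is the standard dPCR assumption and the one the estimator
  inverts.
* Amplitudes: Gaussian clusters — ch1 negatives 1,000 ± 100 vs
  positives 8,000 ± 300; ch2 800 ± 90 vs 6,000 ± 250 (>20 negative-SDs
  of separation, on the amplitude scale of the QX200 reader). A
  rain_fraction (default 2%) of positive droplets lands uniformly
  between the cluster means instead, emulating partially amplified
  droplets. Blanks force both concentrations to zero with rain off.
* Artifacts seen in crude lysate without viscosity-breakdown
  pre-treatment: `no_vb_diagonal` adds one shared Uniform(0, s) offset
  to both channels for a configured fraction of droplets (a diagonal
  smear in the 2-D plot) and multiplies the droplet count by a
  reduction factor < 1; `shifted_dn_cluster` relocates a fraction of
  double-negative droplets upward in ch1 by a fixed offset (the
  cluster that manual gating excludes). The artifact geometry is
  illustrative — no published parameterization exists — so fractions,
  scale and reduction are free knobs.
* Dilution series are specified on the targets-per-cell scale. The
  stated `cells_per_well` are the genome equivalents that end up in
  droplets: concentrations are computed against the screened volume
  N̄·V̄ (20,000 × 0.70 nL = 14 µL), so that a level of 0.0003
  targets/cell at 2,500 cells contributes exactly 0.75 expected copies
  to a well and ≈3 to a merged 4-well sample. This is the quantity the
  rare-event arithmetic (hit rate ≈ 1 − e⁻³ ≈ 0.95) is about; dead
  volume between mixing and encapsulation is upstream of what the
  generator models.
* Monolayer images: bright discs (intensity 200) with a 2-px darker
  rim (150) on a dark background (20) plus Gaussian read noise (SD 4),
  8-bit. Discs are placed on a shuffled, jittered grid sized by the
  largest diameter, which guarantees non-overlap and fails loudly when
  the canvas cannot hold the request; rejection sampling was rejected
  because it stalls at the ~30% packing fraction a 300-droplet render
  needs.

Everything is driven by one integer seed through `numpy`'s Generator;
identical config + seed reproduces identical wells bitwise.

What the generator does **not** emulate: amplitude drift between wells,
inter-channel spectral crosstalk, droplet coalescence, template
degradation, inhibition gradients across a dilution series, or any
fluidics of droplet formation. Passing tests therefore demonstrate that
the analysis correctly inverts the model the assay is premised on and
is robust to the listed artifacts — not that a particular wet-lab run
meets its specifications.

## Problem sizes and numerical choices

Simulation-based checks use 200 wells of 20,000 droplets for estimator
recovery (signed mean relative error ≈ −0.2%, driven by the 2% rain
default losing ~10% of rain droplets below threshold; CI coverage
93–97%), 100 merged 4-well samples for the rare-event hit rate, 22 + 8
blank wells for the LOB, and 4 × 75 rendered discs for the imaging
round trip — sizes chosen to match the assay's own design (triplicates,
4-well merges, ~300 measured droplets) while keeping a full run in
seconds. The recovery criterion is on the signed mean relative error (a
bias measure); the mean of absolute relative errors is dominated by the
irreducible binomial SE (≈1.8% at λ = 0.1, N = 20,000) and is not a
property of the estimator's correctness.

Tolerances worth knowing: λ̂ agrees with a 40-digit decimal evaluation
to < 10⁻¹²; merged-count and pooled-droplet estimates are identical to
the last bit (same integers in, same floats out); printed-table CV
checks use the table's own precision (4 decimals on replicates, 2 on
CVs).

## Known limitations

* Volume heterogeneity enters the estimate only through the point
  volume used; no multi-volume partition correction (the bias at 3% CV
  of volume and λ ≤ 0.25 is < 10⁻⁴ relative).
* The LOB/LOD/LOQ panel is a single-panel estimate, not a multi-lot,
  multi-day CLSI EP17 design.
* Per-well adaptive thresholds and mixture-model gating are out of
  scope; one threshold pair serves the plate.
* The probit fit reports "degenerate" on separated data instead of a
  penalized fit; a 100%-everywhere table has no identifiable slope and
  pretending otherwise would manufacture precision.
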