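# Methods

This note records the models, conventions and numerical choices behind
`waxtransect`, and what the synthetic tests do and do not demonstrate
about real data.

## Quantification model

Peak areas are converted to absolute amounts against a single designated
internal-standard area: `conc[n] = (area[n]/is_area) · is_amount_ug /
(RF[n] · dry_mass_g)` in µg per g dry leaf.  Defaults are 60 µg of
internal standard per extraction and 0.1 g dry leaf, the masses typical of
accelerated-solvent extractions of milled leaf material.  Internal
standards are often multi-compound mixtures; which compound anchors the
*n*-alkane quantification varies between labs, so the module takes one
reference area rather than modelling the mixture.  Response factors
(RF, default 1.0 per chain) are deliberately user-supplied: calibration
models differ (single-point vs. curve, which chains the standard mixture
covers), and the package does not guess one.  `quantify` is linear in each
area and inversely proportional to dry mass; both properties are tested.

Relative abundances are the compositional view of a profile,
`x_n = C_n / Σ C_n`; they are stored as fractions and printed as
percentages.  An all-zero profile has no defined composition and is an
error rather than a silent row of zeros.

## Chain-length metrics

**ACL** is the concentration-weighted mean carbon number over a window,
C23–C33 by default — the window in which *n*-alkanes are routinely
identified on leaf material, and the one the data cover.  Two conventions
coexist in the literature: summing every measured homolog, and summing
odd homologs only.  The default follows the literal all-chain sum;
`odd_only=True` gives the odd-chain convention.  With an
odd-over-even-dominated profile the two differ by only a few hundredths
of a carbon, but the choice is exposed rather than hidden.  ACL is
scale-invariant, so it is identical on concentrations and relative
abundances (tested property), and bounded by the lowest and highest chain
with positive concentration.

**ratio = C31/(C31+C29)** contrasts the two dominant homologs as a
fraction of one — bounded, variance-standardised and strictly monotone in
each argument.  It is undefined when both chains are zero; such records
are flagged and carried along (`ratio = None`), never dropped, so sample
counts stay auditable.

**Odd-even preference** is reported per odd chain as a strict
local-dominance flag (odd chain > both measured even neighbours).  A
missing neighbour is vacuously satisfied; equality fails.  This
reproduces the qualitative statements transect studies make ("all species
odd-dominated except C23 in some species") without committing to any of
the several numerical OEP/CPI indices.

## Replicate QC and outliers

Replicate measurements (lab re-runs and field splits are treated alike)
share a `replicate_group`.  Per group the package reports CV = 100·SD/mean
(n−1 denominator) of total concentration, each chain's concentration, ACL
and ratio.  Under multiplicative per-compound noise the per-chain CVs sit
near the noise level while ACL's CV is one to two orders of magnitude
smaller, because correlated scale noise cancels from the weighted mean —
the contrast that justifies trusting composition metrics from noisy
absolute yields.

Outlier handling makes an inspection-based judgement ("abnormally small
compared to similar samples at the same site") explicit: within each
(species × site) group of ≥ 3 defined values, a value is flagged when
|value − median| > k·1.4826·MAD, k = 3 by default.  Flags are **advisory**:
exclusion happens only through an explicit exclusion list or an
`auto_exclude` opt-in, and excluded samples are removed from all analysis
with the triggering response and reason recorded.  A known limitation is
intrinsic to the rule at this design's group sizes: with only three values
the MAD degenerates to the smaller of the two spacings, which both misses
genuine outliers (an injected C31 outlier moves the ratio by at most ~6–7
within-group SDs, not enough to clear 4.45× a random spacing reliably) and
over-flags clean data (≈11% of clean normal triplets exceed the k = 3
threshold; still ≈3–5% for groups of 4–8).  The acceptance suite measures
exactly this, and the corresponding check fails by design of the rule, not
by implementation defect.  For small groups the flags should be read as a
screening aid for the analyst, which is why they are advisory.

## Correlation analysis

Spearman's rank correlation, authored in the package: average ranks for
ties, *r*ₛ as the Pearson correlation of the ranks (the tie-corrected
form — relevant because humidity values cluster tightly and tie readily at
logger precision).  Two-sided p-values: exact by full enumeration of the
n! permutation null for tie-free samples with n ≤ 9 (the null |*r*ₛ|
distribution is enumerated once per n and cached), t-approximation with
n−2 degrees of freedom otherwise.  Whether published transect analyses
used exact or asymptotic p-values is generally unstated; the scheme used
here is recorded in the output metadata.  Zero-variance inputs yield an
explicitly undefined result with a reason code — never a fabricated 0.

Two designs: **species response** (one test per species × response ×
covariate, restricted to species with non-excluded samples from ≥ 3
distinct sites) and **site total response** (all species pooled).
Responses are ACL, ratio and the odd-chain relative abundances (odd chains
dominate the higher-plant signal); covariates are MAT, RH and MAP.
Significance is strict p < α with α = 0.01 and no multiple-testing
correction — the convention in this literature, with α kept low because
the analysis is a battery of correlations; the number of tests is
annotated on the output instead.  Undefined or under-powered cells are
emitted with reasons so the output cardinality is always predictable.
The three covariates are driven by the same elevation gradient and are
therefore mutually rank-correlated; the analysis reports all three rather
than attempting to attribute the signal to one of them, and a property
test asserts this collinearity is present and preserved.

## Synthetic transect generator

The generator reproduces the statistical structure the analysis assumes,
with defaults fixed at the study conditions it emulates:

* **Sites**: 14, evenly spaced over 653–3,507 m.  MAT = 21.6 °C at the
  lowest site, falling at 14.4 °C/2,854 m (the lapse implied by a
  7.2–21.6 °C range over that relief), site noise SD 0.3 °C.  RH
  99.8→96.1 % and MAP 2,448→1,580 mm, linear in elevation with noise SD
  0.15 % and 30 mm, both oriented so MAT, RH and MAP are mutually
  positively rank-correlated.  The within-site noise SDs are assumptions
  (field studies rarely publish them), chosen small enough to keep the
  covariates' elevation ranks nearly intact.
* **Species**: six models with overlapping elevation bands (8+7+6+4+3+2
  occupied sites; at 3 individuals per occupied site this gives 90 base
  samples, emulating a sampling campaign of ~87).  Each species has a
  Gaussian chain-length envelope (centres 28.8–30.1, widths 1.5–2.0
  carbons) discretised over C23–C33, odd chains multiplied by an OEP
  factor 8–11, and in three species C23 additionally damped (×0.08) to
  produce the C23 anomaly.  Environmental response is an envelope-centre
  shift, β carbons per covariate unit about the transect mean — one
  interpretable parameter per covariate rather than eleven per-chain
  slopes, the simplest mechanism that yields the canonical
  "shorter chains down, longer chains up" pattern.  Default βs:
  +0.15 carbons/°C for two mid-elevation species, −0.08 for one (responses
  vary in sign and magnitude between species), a humidity/precipitation
  response for the wide low-elevation species, +0.15 carbons/°C over a
  deliberately short gradient for the summit species (detectable effect,
  underpowered sampling), and zero for the two-site species that falls
  below the eligibility rule.
* **Measurement model**: total concentration lognormal (mean 60 µg/g,
  CV 0.5 — realistic spread of absolute wax yields), times the expected
  composition, times independent per-compound lognormal noise with
  CV 0.15.  Replicate groups (two triplicates, one duplicate, three field
  splits of two = 14 measurements) re-measure a sample's expectation with
  fresh noise.  Two outliers are injected by multiplying C31 by 0.1,
  mimicking abnormally small values; the truth table records their ids.
* **Reproducibility**: every draw comes from a stream seeded by (master
  seed, entity key), so the same configuration is bit-identical and adding
  a species does not perturb other species' draws.

What the generator does **not** model: biological between-individual
variation beyond measurement noise (leaf age/size effects are absorbed
into `noise_cv`), spatial autocorrelation beyond the shared elevation
dependence, chain-specific response slopes, phenology, or any mechanism of
wax biosynthesis.  Passing tests therefore certify the pipeline's
statistical machinery — calibration, power at programmed effect sizes,
metric robustness — not that real leaf waxes behave this way.

## Pipeline conventions

Stage order is fixed: read/validate → replicate QC (full resolution) →
replicate collapse (per-chain mean per group, one row per physical
sample) → metrics → outlier flags → exclusions → correlations → report.
Collapsing replicates before correlation keeps each physical sample at
unit weight; the alternative (using every measurement) would
pseudo-replicate sites.  Row conservation is checked on every run:
`input rows = analyzed + excluded + invalid + replicate-collapsed`, and
the manifest records the counts with input/output SHA-256 digests; output
digests are deterministic given inputs and seed (the timestamp is
informational only).  Invalid rows are collected and counted rather than
aborting the run; structurally absent chain columns mean "not measured"
and are distinct from recorded zeros ("below detection"), with
`absent_as_zero` available to collapse the two.

## Problem sizes used in the automated checks

Metric oracles run on 1,000 random profiles at 1e-12 relative tolerance;
Spearman exactness enumerates all permutations for n ≤ 7; null
calibration uses 2,000 independent simulated tests (band: 3 Monte-Carlo
SE around 1%); parameter recovery and the outlier study use 200 seeds /
datasets; the CV contrast uses 40 simulated triplicate groups.  These
sizes put Monte-Carlo error comfortably below the asserted margins while
keeping the whole suite fast to run routinely.
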