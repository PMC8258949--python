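# Methods

## Model overview and assumptions

The package estimates the burden of an autosomal-recessive ultra-rare
disease from population allele frequencies. The chain is:

    variant filter → aggregate q per gene → q², 2pq under HWE
    → annual incidence I_y = q²·B_y → life-table aging → prevalence

Assumptions inherited from the modelling approach:

- **Hardy–Weinberg equilibrium** within each gene: random mating, no
  inbreeding adjustment (F = 0), no mutation–selection dynamics. q² then
  counts homozygotes and all within-gene compound heterozygotes exactly,
  because (Σqᵢ)² = Σqᵢ² + Σ_{i≠j} qᵢqⱼ.
- **Cross-gene compound genotypes are negligible** — at aggregate
  frequencies of 10⁻⁴–10⁻³ per gene the cross terms are ~10⁻⁶ of the
  estimate.
- **Genotype prevalence is constant over the historic window**: the
  allele frequencies measured in present-day cohorts are applied to
  every birth year. Selection against the allele over fifty years at
  these frequencies is far below the confidence width.
- **One mortality model for all genetic subtypes and severities.**
  Milder phenotypes will therefore be underestimated, since undiagnosed
  long-lived patients violate the shared life table.
- **No fetal-mortality adjustment**: q²·B_y treats genotype prevalence
  at conception as prevalence at live birth.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| confidence level | 0.95 | — | standard reporting convention for this model class |
| anchor year | 2018 | calendar year | year whose births define the headline incidence |
| reference year | 2020 | calendar year | evaluation date for "current" prevalence; config-exposed |
| historic window | reference − 34 … reference | years | cohorts older than max lifespan contribute nothing |
| max lifespan | 34 | completed years | hard cutoff: S(35) = 0 regardless of rates |
| early survival | 0.75 to age 5 | probability | natural-history calibration constraint |
| mid-childhood rate | 0.02 | /yr, ages 5–14 | see "Default life table" below |
| adult rate | 0.08 | /yr, ages 15–34 | uniform adult hazard |
| cohort size (simulation) | 125,000 individuals | persons | scale of the sequencing datasets emulated |
| survival cohort (simulation) | 66 patients | persons | scale of the natural-history study emulated |

## Default life table

Only one quantitative constraint on early-childhood mortality is
available: about 75% of patients survive to age five. The default table
therefore uses a three-segment parameterization: ages 0–4 share the
constant rate r₀ = 1 − 0.75^(1/5) ≈ 0.0559, which reproduces
S(5) = 0.75 *exactly*; ages 5–14 use 2%/yr; ages 15–34 use 8%/yr.

The 2%/yr middle segment is this package's choice: the published
per-age rates for ages 0–14 are not recoverable, and 2%/yr gives a
smooth decline between the early-childhood and adult segments,
consistent with the qualitative observation that most deaths occur
early. Any user-supplied per-age vector (CSV: `age,
annual_mortality_rate`, contiguous ages 0..max_age) overrides the
default entirely — the life table is data, not code. Consequently,
tests of the mortality module target the machinery (survival recursion,
cutoff, calibration) rather than any specific historical rate vector.

Deaths occur at year boundaries (discrete life table); age is completed
years at the reference date, so a cohort born in year b has age
reference_year − b.

## Confidence intervals and their propagation

Allele-frequency intervals use the Agresti–Coull ("modified Wald")
construction with the exact normal quantile z (not the z² = 4 classroom
simplification; that variant is available behind `simplified_z` since
the method is often quoted that way, and the two agree to reporting
precision at 95%). Bounds are clamped to [0, 1] after construction.

**Multi-site pooling.** How the original analysis pooled intervals
across variants with different AN is not documented, so the strategy is
explicit and named: the default forms an effective binomial with
x = round(q̂·n̄) and n = n̄ = mean AN over included sites, which recovers
the single-site interval exactly when all AN agree; `min_an` is the
conservative alternative (widest interval). Because x is rounded, the
interval can in principle miss q̂ by a hair; the aggregate widens the
interval minimally to contain q̂ and flags this via `clamped`, keeping
the (lo ≤ point ≤ hi) invariant.

**Propagation** is strictly componentwise (lo with lo, hi with hi)
through squaring, 2pq, scaling by births/population, and summation over
cohorts and genes. This is valid because every transform is monotone:
x² on [0, 1] and 2x(1−x) on [0, 0.5] — carrier conversion refuses
q.hi > 0.5, outside the monotone region and far outside the model's
rare-allele domain. No delta method or resampling is used, matching the
model's design of reusing the allele-frequency bounds throughout.
Mortality-model uncertainty is deliberately not propagated; only
allele-frequency uncertainty is.

**Empty genes.** A gene with zero included variants in a dataset is a
real outcome, not an error (an allele can be absent from one cohort).
Its point estimate is 0 with the zero-success upper bound at a fallback
allele number — the pipeline uses the dataset's mean AN, since the
zero-count interval still needs a sample size and the spec of the
original analysis provides none.

## Filtering rules and tie-breaks

The decision order is: region restriction → clinical benign → clinical
pathogenic → predicted LoF → SIFT/PolyPhen-concordant missense →
excluded. Two tie-breaks are this package's decisions, surfaced in
every output via `rule_fired`:

- Clinical evidence beats predictions in both directions ("uncertain
  significance" falls through to the prediction rules).
- PolyPhen "possibly damaging" counts as damaging (the permissive
  reading of "deleterious or damaging by both tools");
  `possibly_damaging_is_damaging=False` switches to the strict reading.

Non-canonical splice-region variants are never auto-included — cryptic
splicing is not reliably predictable from consequence labels — so they
enter only via a clinical pathogenic report. Per-gene genomic interval
restrictions (e.g. a PTS2-domain region for *PEX5*) are config inputs,
1-based closed intervals; no coordinates are hardcoded.

## Reporting conventions

Births are displayed to 1 decimal, carriers to the nearest thousand,
patients to the nearest integer. Totals are computed on unrounded
values and then rounded half-up; this sum-then-round convention is the
one that reproduces published summary rows from their per-gene entries
(per-gene bounds summing to slightly different printed totals is a
rounding artifact of the alternative). `round_then_sum` is available as
a report flag for comparison. Multi-region combination sums the
regional bounds componentwise.

## Synthetic data: what it does and does not emulate

The generator draws per-variant allele counts AC ~ Binomial(2N, qᵢ)
with N = 125,000 individuals per dataset, splits each gene's true
aggregate frequency across variants (fixed proportions or Dirichlet),
emits decoy variants engineered to be rejected by each exclusion rule,
and writes a truth sidecar for recovery tests. Birth series are level
+ optional trend + bounded Gaussian noise; survival cohorts draw age at
death from the life table's implied distribution.

It emulates: sampling noise of rare allele counts at realistic cohort
scale, gene-level frequency structure, filter-relevant annotation
combinations, multi-region frequency sharing.

It does **not** emulate: linkage between sites (the model itself
assumes independent alleles, so synthetic data matches the model's
assumptions by construction), sequencing error, coverage-dependent AN
variation, population substructure, or ancestry-specific allele
sharing. Passing tests therefore demonstrate correctness of the
arithmetic and calibration of the intervals *under the model's own
assumptions* — they do not validate those assumptions against real
cohorts, where substructure or annotation error could bias q.

The five-gene "paper-like" preset (one dominant gene near q = 1.7×10⁻³,
half truncating; one intermediate; three near-zero, one with a region
restriction) is an order-of-magnitude demonstration, not a reproduction
of any specific published frequency list, which would require the real
supplementary variant table.

## Numerical choices and degenerate inputs

- Survival uses cumulative products in float64; at 35 ages the rounding
  error is ~10⁻¹⁵ relative, far below any reported precision.
- Gap-filling of birth series: a missing year takes the value of the
  nearest available year, ties toward the earlier year; every filled
  year is flagged in the report provenance.
- AC > AN, non-positive AN, negative positions, duplicate region-years,
  non-contiguous mortality ages, and q triplets with lo > point are all
  rejected with messages naming the offending variant/row.
- Problem sizes in the test suite (500-replicate recovery runs at
  AN = 250,000, 2000-draw coverage checks, 20–25 randomized oracle
  configurations) were chosen as the smallest sizes at which binomial
  Monte-Carlo error is decisively smaller than the tolerance bands
  being asserted.

## Known limitations

- Severity/genotype-specific survival is out of scope; a single life
  table is applied to all subtypes.
- EU5 is one pooled region with one frequency set applied uniformly;
  no country-level decomposition or migration modelling.
- Carrier counts use the total population size as denominator
  (config-exposed), not an age-restricted one.
- Annotation quality is an input: the package does not run SIFT,
  PolyPhen or any splice predictor, and canonical-isoform annotation is
  assumed present.
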