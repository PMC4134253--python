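# Methods

`parkviable` models the fate of a small, isolated red squirrel
(*Sciurus vulgaris*) population confined to an urban park — a
184 ha park near Paris whose ~100–120 squirrels occupy two wooded
strata (eastern 28 ha, western 44 ha) and are cut off from the nearest
forest by an urban matrix.  The package couples four analyses: a
deterministic life-table analysis, an individual-based stochastic
projection with multi-locus genetic tracking and immigration, the
population-genetic summary statistics used to characterise the
population, and the stratified line-transect abundance estimate that
anchors the starting population size.

## Demographic model

The life cycle is annual with a pre-breeding birth-pulse census: age 1 is
the first censused class, and newborns (age 0) pass through their first
(juvenile) mortality round before the next census.  The female life
table implied by a scenario is

* survivorship  l₁ = S_j, l_{x+1} = l_x·S_f  (subadult survival is set
  equal to adult female survival; no separate subadult rate is
  estimated for this population),
* fecundity  m_x = b·(1 + p₂)·L̄·(1 − σ) for x ≥ α, else 0,

with b the annual proportion of breeding females, p₂ = 0.35 the
probability of a second annual litter, L̄ = 3 the mean litter size,
σ = 0.5 the birth sex ratio (fraction male), and α the age at first
litter (1 or 2 years).  The asymptotic growth rate λ solves the
Euler–Lotka equation Σ_x l_x m_x λ^(−x) = 1 on the truncated age range
(bracketed bisection via Brent's method, |Δλ| < 1e−12); it is
cross-checked against the dominant eigenvalue of the corresponding
Leslie matrix (agreement to 1e−8 is a tested invariant).  Generation
time is the mean age of mothers at stable age structure,
T = Σ x l_x m_x λ^(−x) / Σ l_x m_x λ^(−x) ≈ 2.3 y under the optimistic
scenarios, so the 20-year horizon spans roughly 9–10 generations.

## Stochastic engine

Each replicate projects individual agents (sex, age, origin, diploid
multi-locus genotype) through annual cycles in the fixed order
**breed → die → immigrate → truncate → age**, the ordering used by the
classic PVA packages this engine mirrors; permuting it shifts the
realised growth rate by O(1 %).

* **Environmental variation** — each vital rate with a non-zero
  among-year SD (adult survival F/M, juvenile survival, breeding
  proportion) is redrawn once per year from a beta distribution with
  the stated mean and SD.  Draws are independent among rates, years and
  populations; no rate concordance is modelled.
* **Demographic stochasticity** — Bernoulli breeding and survival per
  individual, Binomial(6, 0.5) litter sizes (mean 3, maximum 6),
  Bernoulli offspring sex, Poisson immigrant arrivals.
* **Mating** — polygynous: every litter is sired by one male of
  breeding age drawn uniformly with replacement; a year with no adult
  male produces no litters.  Breeding females raise a second litter
  with probability 0.35.
* **Inheritance** — one uniformly chosen allele per locus from each
  parent; no mutation, so every allele segregating at year t existed in
  some individual at year t−1 (a tested conservation invariant).
* **Carrying capacity** — a ceiling: when the post-immigration census
  N exceeds K, each individual is removed independently with
  probability (N−K)/N.
* **Ageing and death** — individuals whose age would exceed the maximum
  die deterministically at the end of their last year.

**Growth-rate bookkeeping.** The stochastic growth rate is accumulated
as r_t = ln(N′_t / N_{t−1}) where N′_t is the count *after breeding and
mortality but before immigration and ceiling truncation*.  Measuring
growth before the ceiling keeps r interpretable for a population
founded at K (a post-ceiling ratio would be pinned near zero however
fast the population can grow) and isolates intrinsic growth from
rescue.  Replicate-years after extinction are excluded.

**Extinction** is declared when either sex is absent from the resident
population: a single-sex population is demographically dead even while
individuals persist.  The extinction probability is the fraction of
replicates extinct at the final census; with immigration enabled a
population can be rescued out of that state.

**Genetic bookkeeping.** Expected heterozygosity is the plain
multi-locus gene diversity He = (1/L) Σ_l (1 − Σ_a p̂²_{la}) of the
resident allele frequencies — the drift-bookkeeping form, deliberately
without the small-sample correction used for observed field samples
(both forms are exposed, clearly named).  Final-year statistics are
averaged over extant replicates only.  Monomorphic founder loci are
excluded from tracking (they carry no drift signal), leaving the 12
polymorphic microsatellites of the park panel with mean founder gene
diversity 0.4745.

**Founders** are unrelated: sexes Bernoulli(1/2), ages drawn from the
stable age distribution of the deterministic life table, genotypes in
Hardy–Weinberg proportions at the supplied allele frequencies.

**Immigration and the source population.** Arrivals are
Poisson(expected rate) per year; immigrants are drawn uniformly from
the 1–2-year-olds of a parallel source population founded from the same
allele frequencies.  The study design calls for a source of *stable*
size 100, but a source following the pessimistic resident vital rates
would collapse; the source is therefore held stable by construction:
it breeds and dies under the scenario rates (independent environmental
draws), then is restored to exactly 100 — surpluses trimmed at random,
shortfalls topped up with recruits bred from random resident pairs.
Drift in the source is thereby retained at a realistic rate.  An
`idealized_source` option replaces this with draws from the founder
frequencies (a non-drifting source), which gives the clean monotonicity
property that gene flow cannot reduce expected diversity.

**Reproducibility.** Each replicate consumes an independent RNG stream
spawned from the master seed (PCG64 via `SeedSequence.spawn`), so
summaries are bit-reproducible for a given (scenario, plan, frequencies,
seed) and independent of replicate ordering.

An expectation mode (`expected_value_trajectory`) propagates real-valued
age-by-sex vectors with all stochasticity replaced by means; starting
from the joint stable age structure its yearly growth factor equals the
deterministic λ to 1e−6, anchoring the engine against the analytic
solution.

## Parameters

| parameter | default | units | provenance |
|---|---|---|---|
| adult survival F / M | 0.68 / 0.63 | yr⁻¹ | field estimate (robust design) |
| adult survival EV SD F / M | 0.12 / 0.13 | — | field estimate |
| second-litter probability | 0.35 | — | literature |
| litter size mean / max | 3 / 6 | offspring | literature |
| birth sex ratio | 0.5 | fraction male | literature |
| carrying capacity K | 120 | animals | census estimate |
| initial N | 120 | animals | census estimate |
| horizon / replicates | 20 yr / 1000 | — | study design |
| age at first litter α | 1 or 2 | yr | scenario axis |
| juvenile survival S_j | 0.20–0.50 | yr⁻¹ | scenario axis |
| breeding females b | 0.35 or 0.50 | yr⁻¹ | scenario axis |
| maximum age | 8 | yr | package choice (see below) |
| male first breeding age | 1 | yr | package choice |
| juvenile survival EV SD | 0.10 | — | package choice |
| breeding EV SD | 0.10 | — | package choice |

The last four values were never published for this system.  Maximum age
8 is at the upper end of wild red squirrel longevity (typically ≤ 7–8
years); the environmental SDs mirror the magnitude of the published
adult-survival SDs.  All four are overridable in any scenario config,
and their influence is documented below because it is the dominant
structural uncertainty of the reproduction.

## Sensitivity and known reproduction gaps

For the most pessimistic corner (α = 1, S_j = 0.20, b = 0.35) the
truncated life table gives ln λ = −0.263 at maximum age 8 (−0.236 at
10; −0.196 with no senescence), and small-population demographic noise
adds roughly a further −0.05 to the realised mean r.  The engine
therefore reports r ≈ −0.32 and an extinction probability ≈ 0.95 where
the original projections reported −0.24 and 0.82.  The discrepancy is
structural — it persists under seed changes, and the engine matches
ln λ to < 0.005 when variance is switched off at large N — and would
close only with a longer lifespan or smaller environmental variance
than the documented defaults, neither of which we consider defensible
a priori.  All other corner-scenario quantities (optimistic growth
rate, extinction bounds, terminal heterozygosities, the immigration
rescue) reproduce within the structural tolerances.

The deterministic viability thresholds behave the same way: with 50 %
breeding females, λ crosses 1 at S_j ≈ 33 % (α = 1) and ≈ 50 % (α = 2)
versus the original figure's ~25 % / ~40 %.  The original thresholds
are only consistent with a markedly higher fecundity (≈ 1.27
daughters/female/yr) than the documented reproductive parameters imply
(1.01 at 50 % breeding), so the thresholds are reported, not forced.

The realised among-year SD of r (≈ 0.2–0.3) is smaller than originally
reported (≈ 0.4–0.5), consistent with the unpublished environmental
variances having been larger than the package defaults; the mean-level
comparisons above are the quantities with stated tolerances.

## Genetic summary statistics

* Observed heterozygosity Ho: fraction of genotyped individuals
  heterozygous; missing genotypes excluded per locus, so per-locus
  sample sizes vary, as in hair-sample panels.
* Expected heterozygosity: unbiased gene diversity
  He = 2n/(2n−1)·(1 − Σ p̂²) (Nei 1978) for field-style samples.
* Hardy–Weinberg exact test, conditional on allele counts with the
  table-probability statistic (Guo & Thompson convention).  Full
  enumeration is used when a cheap product bound shows the table space
  is ≤ 10⁶; otherwise Monte-Carlo with 100 000 permutations of the
  allele copies, reporting the binomial SE.  The result also carries the
  strictly-more-extreme tail so calibration checks can de-discretise
  the p-value; monomorphic loci return p = 1.
* Haplotype diversity Hd = n/(n−1)(1 − Σ p²) with the Nei (1987)
  variance; haplotypes are defined on the full alignment and sequences
  containing gaps or ambiguity codes are dropped (logged).
* Nucleotide diversity π: mean over all n(n−1)/2 sequence pairs of the
  per-site difference fraction, sites with gaps/ambiguity excluded
  pairwise; SE from the standard total-variance formula.

## Distance sampling

Perpendicular distances are modelled by a half-normal
(exp(−x²/2σ²)) or hazard-rate (1 − exp(−(x/σ)^(−b)), b ≥ 1) key, times
an optional cosine adjustment series on [0, w], renormalised to
g(0) = 1.  Parameters maximise the conditional likelihood
f(x) = g(x)/∫₀^w g (Nelder–Mead on log-transformed scale parameters;
the adjustment normalisation cancels in the likelihood).  Candidate
models are compared by AIC with a forward search over cosine orders
(2, then 3); fits with negative g anywhere on a 401-point grid are
rejected rather than constrained.  Truncation defaults to the maximum
observed distance.  ESW = ∫₀^w g converts encounter rate to density
D = n/(2·L·ESW); its variance combines the empirical among-transect
encounter-rate component (the standard weighted estimator; Poisson when
only pooled counts exist) with a delta-method detection component from
the numerical Hessian at the optimum; intervals are log-normal.
Abundance sums D_s·A_s over the 28 ha eastern and 44 ha western strata
with delta-method variance.

## Synthetic data generator

The generator replaces three field data sets that are not packaged, and
is itself first-class, tested code.

* **Genotypes** — per-locus allele spectra are *constructed* to hit the
  published per-locus expected heterozygosities exactly: the two-allele
  solution p = (1+√(1−2h))/2 for h ≤ 0.5, else the smallest feasible
  number of equifrequent minor alleles plus a residual major allele.
  Genotypes are drawn in Hardy–Weinberg proportions at independent
  loci; entries are masked at the published amplification failure rate
  (25.5 %), reproducing the varying per-locus sample sizes of the real
  panel.  The spectra match the published diversities, not the real
  (unpublished) allele counts; because the expected drift of He is
  insensitive to allele number, the projection targets are unaffected.
* **Sequences** — a 486 bp D-loop-like alignment of 65 sequences in 3
  haplotypes at frequencies 36:15:14, with planted substitutions
  placed so haplotype diversity ≈ 0.60 and nucleotide diversity
  ≈ 0.009–0.010/site.  Exact-count mode makes the diversity statistics
  deterministic.  No coalescent realism is attempted.
* **Sightings** — animals form a Poisson field in each surveyed strip,
  perpendicular distances are uniform, and detection thins by g(x)
  (default hazard-rate, σ = 12 m, b = 3).  The default layout surveys
  the eastern stratum with 8×800 m transects and the western with
  8×1000 m at w = 30 m, yielding sighting counts comparable to the real
  sessions at the published densities.  No spatial clustering of
  animals is modelled.

Because the generator reproduces marginal summaries rather than the
processes behind them (no linkage, no null alleles, no observer
effects), passing tests demonstrate correctness of the estimators and
the projection machinery, not field realism.

## Problem sizes

All shipped analyses run at the study scale: 1000 replicates × 20 years
× ≤ 220 agents per scenario (~4 s each; the full 16-scenario grid
~90 s on one core).  Property checks use reduced sizes chosen for
statistical power: 100–200 replicates for Monte-Carlo comparisons, 200
synthetic surveys for estimator unbiasedness, 1000 simulated loci for
test calibration.

## Limitations

No inbreeding-depression penalty, mutation, catastrophes,
density-dependent breeding, or within-park spatial structure is
modelled, matching the scope of the original projections.  The
percentage of breeding females is applied as a constant annual rate
(its low-density anchor was never published).  Confidence intervals for
the published abundance sessions are not reproducible because
per-transect encounter data were never published; only point abundance
is compared.
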