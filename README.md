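# parkviable

Demographic–genetic population viability analysis (PVA) for a small,
isolated urban population of the Eurasian red squirrel (*Sciurus
vulgaris*).

Urban parks can hold surprisingly healthy wildlife populations, but a
hundred squirrels behind an urban matrix face the twin small-population
hazards: demographic/environmental stochasticity (extinction risk) and
genetic drift (loss of heterozygosity).  `parkviable` is built for
conservation analysts asking the questions that decide whether such a
park is a refuge or a trap: *under which vital rates does the
population grow, how likely is extinction within 20 years, how fast
does gene diversity erode in isolation, and how much immigration buys
it back?*

The package implements, end to end:

* **Deterministic demography** — female life tables, the Euler–Lotka
  growth rate λ (cross-checked against the Leslie-matrix eigenvalue)
  and generation time, over a grid of juvenile survival S_j and age at
  first litter;
* **A stochastic individual-based simulator** — yearly cycles of
  polygynous breeding, Bernoulli survival, beta-distributed
  environmental variation, a ceiling carrying capacity K, Mendelian
  inheritance at 12 microsatellite loci, and Poisson immigration from a
  stable source population of 100;
* **Population-genetic statistics** — allele frequencies, observed and
  unbiased expected heterozygosity (Nei 1978), exact Hardy–Weinberg
  tests (Guo & Thompson statistic; enumeration or Monte-Carlo),
  haplotype and nucleotide diversity of mtDNA alignments;
* **Line-transect distance sampling** — half-normal and hazard-rate
  detection functions with cosine adjustments, AIC model selection,
  ESW-based stratified densities and park-wide abundance
  (D = n / (2·L·ESW), N̂ = Σ D_s·A_s);
* **A synthetic-data generator** producing study-shaped genotype
  tables, D-loop alignments and sighting records, so every stage is
  testable without any field data.

The central quantities follow standard notation: stochastic growth
rate r = mean ln(N_{t+1}/N_t) over replicate-years, extinction
probability PE, gene diversity He = 1 − Σp².  See `docs/methods.md`
for the full model description and design choices.

## Worked example

Project the most optimistic scenario (first litter at 1 year, 50 %
juvenile survival, 50 % of females breeding) for a population founded
at the park's carrying capacity, tracking founder allele frequencies
matched to the observed microsatellite diversity:

```python
import parkviable as pv
from parkviable.synth import sceaux_frequencies

model = pv.PVAModel(
    pv.LifeHistoryScenario(
        age_first_litter_f=1, juvenile_survival=0.5,
        prop_females_breeding=0.5,
    ),
    freqs=sceaux_frequencies(),
)
print(model.simulate(seed=1).summary())
```

```
Stochastic population viability projection
==============================================
scenario: age at first litter 1 y, juvenile survival 50%, breeding females 50%
N0 = 120, K = 120, 20 years x 1000 replicates (seed 1)
immigrants/year: 0.0
----------------------------------------------
stochastic r:           0.144 (SD 0.18)
P(extinction):          0.000
mean final N:           114.8
initial gene div.:      0.473
final gene div.:        0.436 (SD 0.03)
```

Read: the population grows intrinsically (r ≈ 0.14/yr, i.e. ~15 %/yr
before the ceiling bites), essentially never goes extinct within 20
years, sits at carrying capacity — yet still loses about 8 % of its
gene diversity (0.473 → 0.436) to drift, because a census of ~120
squirrels is an effective population of only a few dozen.
`model.deterministic()` gives the matching analytic anchors
(λ = 1.180, generation time 2.26 y).  Under the most pessimistic
scenario the same call yields r ≈ −0.32 with near-certain extinction,
and adding `plan=pv.ImmigrationPlan(expected_immigrants_per_year=3)`
shows immigration holding final He near 0.41 even there.

The command line mirrors the library
(`parkviable run|grid|lambda|genetics|distance|synth`, each writing a
reproducibility manifest beside its output):

```bash
parkviable grid --seed 1 --reps 1000 --out grid.csv   # 16-scenario grid
parkviable lambda --sj-grid 0:0.6:0.01 --out lambda.csv
parkviable synth sightings --seed 7 --out-dir survey/
```

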