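# Methods

## Model and procedure

The package studies transmission-based rare-variant association tests in
parent–offspring trios under non-symmetric genotype-calling error. The core
objects and steps:

**Trio simulation.** A panel fixes, per variant, a rare-allele population
frequency f and a gene assignment. Parental dosages are drawn Binomial(2, f)
(Hardy–Weinberg); each parent transmits one uniformly chosen allele, so the
child's true genotype is Mendelian-consistent by construction and the
per-parent transmitted allele is recorded for oracle checks. Variants are
simulated independently — there is no linkage disequilibrium (see
Limitations).

**Error model.** Two flip types, applied independently per
(individual, variant) cell of the observed layer: a heterozygote called
hom-ref with probability r1, and a hom-ref called het with probability r2.
Four scenarios place one flip type in one generation (r1 in parents /
offspring; r2 in parents / offspring). Hom-alt calls are never altered: the
modelled error modes do not produce them and rare-variant hom-alt genotypes
are second-order rare. Errors are unclustered (flat rates). The injector
consumes one uniform draw per cell in a fixed order, so with a shared seed
the flip sets at two rates are nested — condition grids can be run as
coupled comparisons on identical cohorts, which is how the monotonicity
analyses are performed.

**Counting.** For each trio-variant cell with complete genotypes, the triple
(father, mother, child) is screened for Mendelian consistency: child dosage
must lie between the number of hom-alt parents and 2 minus the number of
hom-ref parents. Inconsistent cells are excluded *at that variant only* and
tallied as exclusions (the whole trio is not discarded genome-wide, matching
standard per-SNP TDT practice). For a consistent triple with h het parents
and a hom-alt parents, the het parents jointly transmitted t = child − a
rare alleles and withheld h − t; the double-het, het-child triple
contributes (1, 1) — which parent transmitted is ambiguous, the aggregate is
not. Any missing member drops the cell without counting it as an exclusion.
The counted allele is always the panel-defined rare allele, never
re-polarised from sample frequencies.

**Tests.** Single-marker: TDT = (p − q)²/(p + q) against chi-square(1);
p + q = 0 yields an undefined statistic and p-value 1. Gene level: member
variants' (p, q) are summed and the same statistic applied to (P_g, Q_g) —
a collapsed-count TDT. This is implemented as the natural gene-based
extension of the marker test; it reproduces every gene-level behaviour the
evaluation targets (inflation direction, rate monotonicity, gene-length
dependence). No multiple-testing correction or MAF weighting is applied;
QQ and rate summaries operate on raw p-values.

**Disease model (power studies).** Logistic in the child's causal
rare-allele count k: log-odds = logit(prevalence) + β·k, so a non-carrier is
affected with exactly the baseline prevalence and each causal allele
multiplies the odds by e^β. Affected cohorts are produced by rejection
sampling with a configurable candidate budget; under this ascertainment,
causal alleles of het parents are over-transmitted — the signal the tests
detect. The power study is run *per gene*: each replicate is a single-gene
panel (~19 rare variants, MAF < 0.01) with 30% of its variants causal at
β = log 4, and its own 100 affected trios. This per-gene design is what
makes the ascertainment signal strong (a child typically carries 0 or 1
causal alleles of the tested gene, so affected status is highly informative
about transmission); pooling a thousand causal genes into one cohort would
saturate every child's risk and leave no per-gene contrast. It also
reproduces the characteristic error-free transmitted share of ~60% over all
variants of tested genes.

**Error propagation.** First-order expectations for the aggregate tallies,
per scenario (derivation by enumerating the effect of a single flip on each
consistent triple):

| scenario | T' | U' | mechanism |
|---|---|---|---|
| 1 (r1, parents) | (1−r1)·T | (1−r1)·U | het parent leaves the informative set (transmission → Mendelian exclusion; non-transmission → invisible); share unchanged |
| 2 (r1, offspring) | (1−r1)·T | U + r1·T | transmissions re-labelled as non-transmissions; total conserved |
| 3 (r2, parents) | T (exact) | U + r2·E | every false-het parent adds one spurious non-transmission |
| 4 (r2, offspring) | T + r2·U | (1−r2)·U | non-transmissions re-labelled as transmissions; double-hom-ref flips only create exclusions |

E is the *exposure count*: the number of targeted-parent hom-ref cells. A
true hom-ref parent cannot have a hom-alt child, and every flipped such
cell leaves the triple consistent while adding exactly one non-transmission,
so this definition makes the scenario-3 row exact in expectation rather
than first-order; restricting exposures to hom-ref children would
systematically undercount by O(f). Neglected elsewhere are interactions
that are second order in rate × frequency: both-parents-het cells under
scenario 1, hom-alt-offspring cells under scenario 2, het-child
non-transmissions removed by exclusions. The propagation-vs-simulation test
bounds these biases against 3 Monte-Carlo SE on rare-variant cohorts
(MAF < 0.01), the regime the first-order theory is built for; at
MAF ≲ 0.05 the approximation is still within a fraction of a percent of the
simulated totals (see `results/error_inflation/propagation_check.tsv`).

Percentages are formatted as nearest-integer with ties rounded away from
zero, matching the reference tables' convention.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| maf_cap | 0.05 (type-I) / 0.01 (power) | rare-variant threshold of the panel |
| MAF spectrum | density ∝ 1/f on [1/(2·n_eff), maf_cap], n_eff = 1000 | neutral-like, rare-dominated site-frequency spectrum; an explicit frequency table or callable can be supplied instead |
| n_trios | 100 | trios per cohort |
| type-I panel | 541 genes × Poisson(338) variants | study-scale panel (~182,800 sites) |
| power panel | 1,000 genes × Poisson(19.1) variants | study-scale panel (~19,100 sites) |
| r1 grid | 1%, 5%, 10% | het → hom-ref rates (scenarios 1–2) |
| r2 grid | 0.1%, 0.5%, 1% | hom-ref → het rates (scenarios 3–4) |
| β | log 4 | per-causal-allele log odds ratio |
| causal fraction | 0.30 | fraction of variants causal in power panels |
| baseline prevalence | 0.05 | affection probability of a non-carrier (not pinned by the study design; configurable) |
| α | 0.05 | nominal level for rate estimates |

Type-I cohorts are plain random trios: with no causal variants,
conditioning on an affected child changes nothing, so ascertainment is
vacuous under the null.

## What the generator emulates — and what it does not

The simulator reproduces the statistical structure the evaluation needs:
Hardy–Weinberg parents over a rare-dominated frequency spectrum, fair
Mendelian transmission, gene-structured panels, logistic ascertainment. It
does **not** reproduce: linkage disequilibrium between sites, haplotype
structure (the 1/f spectrum stands in for a population-panel-derived
distribution), de novo mutation (assumed negligible), depth- or
caller-specific error structure (a user maps depth to (r1, r2) externally
if desired), or per-site error-rate heterogeneity. Consequently, passing
tests show that the *counting machinery and error arithmetic* behave as
derived under these idealisations; they do not certify behaviour on real
exome data, where error rates correlate with depth and sites are linked.
One known idealisation gap: the generator's error-free null is exactly
50/50 transmitted, whereas the reference study's null tallies sit at 47/53
for reasons internal to its data pipeline; the table-level analyses
therefore take the printed baselines as *inputs* to the propagation
operator rather than attempting to re-simulate them.

## Numerical and design choices

* **Tie-breaks and degenerate inputs.** p + q = 0 → statistic NaN, p-value
  1. Percentage ties round away from zero. Empty p-value lists, zero-mass
  variant-count specs, frequencies outside (0, maf_cap] and non-trio
  pedigrees are rejected with explicit errors.
* **Discreteness of TDT p-values.** Counts make the null p-value
  distribution discrete, with an atom at 1 of size P(X = n/2); testing
  calibration by a literal KS test against the continuous uniform would
  reject at any realistic scale. The uniformity test instead applies a
  randomized probability-integral transform under each variant's exact
  Binomial(n, ½) null, which is exactly uniform when calibration holds.
  Gene-level calibration is checked where the chi-square approximation is
  sound: at study-scale gene lengths (~1,400 informative events per gene)
  the exact null rejection rate at α = 0.05 is 0.0497.
* **QQ bands.** Rank-i expected quantiles and 95% pointwise bands come from
  the Beta(i, n−i+1) law of uniform order statistics; p-values of exactly 0
  are floored at the smallest positive double before −log10.
* **Seeding.** Every stage takes an integer seed; experiment orchestration
  derives per-replicate seeds from one master seed, and injections within a
  replicate share a seed to couple conditions. Reruns are bit-identical.
* **Problem sizes.** The test suite runs the calibration check at the study
  design of 500 genes × 20 replicate cohorts of 100 trios (10,000 gene
  tests), monotonicity checks on coupled grids at 250 genes × 10 replicates
  (type-I) and 200 gene replicates (power), and the propagation check at 50
  replicates of 100 trios × 5,000 rare variants — sizes chosen so each
  assertion has a clear analytic margin (biases bounded well under 3 SE,
  rate contrasts of tens of rejections against coupled noise).

## Known limitations

* The gene-level statistic is a collapsed-count TDT; gene-based
  transmission tests built on likelihood models may differ in absolute
  p-values, so gene-level results are comparable in pattern, not digit by
  digit, with such implementations.
* First-order propagation ignores rate × frequency interaction terms;
  at common-variant frequencies (f ≳ 0.1) or rates ≫ 10% the neglected
  terms grow and the operator should not be trusted.
* Trios only: no extended pedigrees, no sibling tests. General pedigrees
  analysed as sub-trios would accumulate the same biases.
* The power claim "type-I error can exceed power at high error rates" is
  demonstrated by the monotone pair (inflation up, power down) rather than
  asserted at a specific crossing point, which depends on effect-size
  configuration.
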