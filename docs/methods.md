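# Methods

epistakit implements a complete interaction-analysis chain for
biallelic SNP data on blood-pressure-style traits: iterative genotype
quality control, nearest-neighbor (Relief-family) SNP preselection,
and model-based multifactor dimensionality reduction (MB-MDR) scans
for main effects, SNP×SNP and SNP×environment interactions, with
permutation-based maxT multiple-testing correction and a speedMAXT
early-dropping variant.  This note records the models, the defaults
and why they are what they are, the numerical choices, and the known
limitations.

## Data model

Genotypes are hard calls at biallelic SNPs coded as minor-allele
counts 0/1/2 with an explicit missingness mask; the minor allele is
determined per SNP from observed frequencies, so VCF REF/ALT
orientation never leaks into the coding.  Positions are 1-based.
Phenotypes carry sex, age, systolic and diastolic blood pressure
(SBP/DBP, mmHg) and an antihypertensive-medication flag (BPMEDS).

Two derived traits matter downstream:

* **Hypertension status (HS)**: case iff (SBP > 140 **and** DBP > 90)
  **or** BPMEDS = 1, with strict inequalities.  The compound clinical
  definition is conjunctive in the two pressures; medication alone
  suffices because treatment masks the underlying pressure.  Both
  thresholds are arguments.  Samples missing any of the three inputs
  are excluded *for this trait* (flagged NaN, never silently dropped
  from the table); exclusion is per-trait rather than global, so a
  sample missing SBP still enters a DBP analysis.
* **Age groups**: balanced ordered categories at empirical quantiles
  (default tertiles: young/middle/old).  Samples tied on a boundary
  value all go to the lower group — deterministic, order-stable, and
  group sizes differ by at most the number of boundary ties.

## Quality control

`run_qc` repeats two sample filters then three SNP filters until a
pass excludes nothing, recomputing every statistic on the surviving
data each pass (so cascades — e.g. a SNP whose removal drops a
sample's call rate below threshold — resolve over multiple passes).
Within-pass order: sample call rate, heterozygosity outliers, SNP
call rate, MAF, HWE.  Defaults: sample call rate ≥ 0.97;
heterozygosity within 3 SD of the mean (no flags when the SD is 0);
SNP call rate ≥ 0.98 — evaluated separately in cases and controls
when a binary trait is supplied, failing if either group fails, and
on all samples for continuous-trait-only runs; MAF ≥ 0.01; HWE
p ≥ 1e-5, tested in controls only for binary traits.  All thresholds
are strict "less than" exclusions, so a call rate of exactly 0.97
survives.  MAF is computed as min(f, 1−f), which makes the filters
invariant to which allele is coded; explicit recoding after sample
exclusions is available as `io.recode_minor` rather than being forced
inside the QC loop.

The HWE test defaults to the exact conditional test (enumeration over
heterozygote counts at fixed allele counts, two-sided by summing
configurations no more probable than the observed one); the 1-df
chi-square is available for speed.  The two agree closely in the
decision-relevant tail; near p = 1 the exact test's discreteness
leaves gaps of a few percent even at n = 10⁴, which is irrelevant to
filtering at p < 1e-5.

**Relatedness** uses the method-of-moments IBD decomposition
(Z0/Z1/Z2 from observed IBS counts and HWE expectations;
PI_HAT = Z2 + Z1/2), without small-sample bias-correction factors.
Pairs above PI_HAT 0.1875 (midpoint between second- and third-degree
relatives) are flagged and the lower-call-rate member listed for
removal.  The estimator assumes many independent common SNPs; with
only hundreds of SNPs its noise SD is large, so it should be run on
an LD-pruned, common-variant subset (as the relatedness example
does).  **PCA outliers** are flagged beyond 6 SD (configurable) on
any retained component of the standardized genotype matrix, with rank
truncation for degenerate directions.  **LD** is the squared
genotype-count correlation (composite LD, no phasing); pruning is
greedy left-to-right within a column window, always keeping the
earlier SNP of a correlated pair.

## Relief-family filters

All seven filters (Relief, ReliefF, TuRF, SURF, SURF*, multiSURF,
SURF*nTuRF) score SNPs for a binary affection status by contrasting
genotype differences to nearest neighbors of the other class (weight
up) against neighbors of the same class (weight down).  Distance
between samples is the genotype mismatch fraction (the metric of the
Relief-for-SNPs literature; Manhattan on allele counts is an option),
with missing genotypes skipped pairwise and renormalized — both in
distances and in the per-SNP updates — so high-missingness SNPs are
not systematically favored.  A constant SNP has zero difference in
every comparison and therefore weight exactly 0 under every filter.

Defaults: ReliefF uses k = 10 neighbors and all samples as targets
(deterministic); Relief is the k = 1 special case with seeded target
sampling; SURF's neighborhood threshold is the mean pairwise
distance; SURF* adds beyond-threshold neighbors with inverted signs;
TuRF repeatedly removes the lowest-weighted 10% of remaining SNPs and
recomputes (SURF*nTuRF is TuRF over SURF*), recording each SNP's
removal round so rankings respect rounds before weights.  multiSURF
is ambiguous in parts of the literature ("multiple runs of SURF"):
the default here uses per-target mean-distance thresholds, which
coincides with the published MultiSURF without its dead band; passing
explicit global thresholds instead averages independent SURF runs.
Weight ties in top-k selection break by SNP order, recorded in the
output.

These filters favor marginal effects: a purely epistatic pair with no
marginal signal is often outranked by even modest main-effect SNPs
(the filtering example demonstrates this).  `filter_concordance`
reports, for each filter subset, how many significant interaction
pairs are fully contained in it — the natural compatibility metric
between a filter and an interaction scan.

## MB-MDR

For an ordered factor pair (3×3 genotype grid, or 3×L for a SNP and
an L-level environment; a single factor gives a 1×3 grid):

* **Step 1** tests each cell against all other cells — a 2×2
  chi-square (no continuity correction) of cell membership × affection
  for binary traits, signed by the cell's case enrichment; a Welch
  two-sample t for continuous traits, signed by the mean difference.
  Cells with p ≤ `alpha1` (default 0.1) are labeled H (statistic > 0)
  or L (< 0); everything else, including cells below
  `min_cell_count` (default 10) and cells too small to test, is O
  ("no evidence").  The 0.1/10 defaults follow the conventions of the
  published MB-MDR software; both are exposed.
* **Step 2** pools the H cells against the rest (T_H) and the L cells
  against the rest (T_L), same test family, on the chi-square scale
  for binary and the squared-t scale for continuous traits so the two
  sides are comparable; an empty side contributes 0.
  T_max = max(T_H, T_L).
* **Step 3** permutes the trait across samples — one shared
  permutation per replicate for all pairs, which is what makes maxT
  valid — recomputes every pair's T_max, and takes the per-replicate
  maximum over pairs.  Single-step maxT: a pair's adjusted p is the
  add-one fraction (1 + #{b : max_b ≥ T_max_obs})/(B + 1), which is
  monotone in T_max, ≥ the raw permutation p, and bounded below by
  1/(B+1).  An exhaustive mode enumerates all n! permutations for
  n ≤ 8 and uses the exact-test convention p = #{max_b ≥ obs}/n!
  (identity included), for oracle validation.

Welch rather than pooled-variance t is the continuous default (cell
sizes are wildly unbalanced by construction); a zero-variance
degenerate comparison yields statistic 0.  Significance in Step 1 is
decided by comparing |t| to the exact per-cell critical value; cells
whose |t| is below the normal quantile (a lower bound for every t
critical value) are skipped in bulk, which is what makes the
vectorized permutation kernel fast.

**Co-dominant adjustment** (continuous traits): before Steps 1–3 the
trait is residualized, per pair, on unordered-category indicators of
each factor (two contrasts per 3-level factor; empty levels drop out
of the design) plus any covariates.  Additive or dominant main
effects of either factor are absorbed, so only genuinely non-additive
cell patterns can drive T_max — the simulations show a pure main
effect's pairs dropping to null significance rates while a planted
interaction's power is retained.  Binary-trait adjustment is out of
scope.

**Multiple-testing scope**: correction is within one scan (one trait,
one hypothesis family) only, never across traits or scan types.

## speedMAXT

Estimating adjusted p near a significance level α needs only enough
permutations to resolve that level, and most pairs reveal themselves
as clearly null early.  At every `check_interval` permutations, a
pair is retired when both:

1. its adjusted-p estimate exceeds the Wilson upper confidence bound
   (at `ci_level`, default 95%) around `drop_bound_factor`/m with
   m permutations done (default factor 1.5 — a bound that, in
   genome-scale runs with checkpoints every 10⁵ permutations, retires
   everything not headed for a tiny p); and
2. **futility**: its exceedance count already exceeds
   `alpha_guard`·(B+1) − 1 (default α = 0.05), so it could not reach
   significance even if no further permutation ever matched it.

The futility guard is what makes the variant decision-exact: counts
only grow, so a retired pair is non-significant under plain maxT as
well, and a pair that plain maxT would call significant is never
retired.  Retired pairs keep their current estimate, flagged
`dropped_early`, and leave the permutation-max pool.

Removing pairs from the pool deflates the per-permutation maximum,
which would bias surviving borderline pairs toward significance (by
roughly 0.9·(1 − m/B)·α of adjusted p in expectation).  The engine
therefore tracks, for every post-retirement permutation, the maximum
over the pairs actually evaluated, and at the end *lazily resolves*
any survivor whose significance call could depend on the unevaluated
pairs: exactly those permutations are re-evaluated for exactly the
retired pairs, in chunks with early exit once the running maximum
settles the calls.  The result: the significant set at `alpha_guard`
equals plain maxT's **deterministically**, while clear datasets skip
the retired pairs' tail permutations entirely.

The price of exactness is that guaranteed savings are bounded by the
futility horizon: a zero-count pair is only sealed as significant
when fewer than α·(B+1) permutations remain, so checkpoints should
sit within that horizon of B (e.g. check_interval 480 for B = 500 at
α = 0.05; the default 10⁵ means no checkpoint fires at desk-scale B
and speedmaxt degenerates to plain maxT).  On datasets where a pair
sits exactly at the significance boundary, resolution can claw back
the entire saving; across a 50-dataset suite the aggregate saving
remains strictly positive and no seed ever costs more than plain
maxT.  Reported p values for survivors are exact whenever resolution
ran for them; sealed clear winners may report a p deflated by at most
the tail fraction, never across the α boundary.

## Synthetic data

The generator emulates the structure a hypertension-cohort analysis
must survive, not any particular dataset:

* per-SNP MAF drawn uniformly from `maf_range` and genotypes under
  HWE;
* LD blocks from a shared latent standard-normal haplotype factor
  thresholded at the MAF quantile (a Gaussian copula): tunable
  within-block correlation without a coalescent dependency;
  correlation 1 duplicates columns exactly;
* HWE violations via an inbreeding-style excess-homozygosity
  parameter F (genotype probabilities q² + Fpq, 2pq(1−F),
  p² + Fpq; default F = 0.3);
* related pairs by copying whole genotypes with probability equal to
  the relatedness parameter, so PI_HAT ≈ that parameter —
  deliberately a sharing model, not a pedigree;
* missingness injected uniformly or concentrated in designated SNPs
  to force call-rate failures;
* traits from additive penetrance/mean-shift tables over one or two
  loci or locus×environment ("XOR" tables, which shift risk when
  exactly one locus is heterozygous, give pure epistasis with no
  marginal effect at MAF 0.5);
* a cohort wrapper adds age (uniform 20–80), sex, SBP/DBP with an age
  trend and Gaussian noise, and a medication flag whose odds rise
  with measured SBP, placing hypertension prevalence near the ~12%
  typical of adult cohorts.

Everything is seeded and bit-reproducible.  What the generator does
*not* emulate: realistic human LD maps, ascertainment, pedigree
structure, genotyping-batch artifacts, or covariance between
missingness and genotype.  Passing tests therefore demonstrate the
statistical machinery (error control, power on planted signals,
estimator agreement), not performance on real cohort idiosyncrasies.

## Validation design and problem sizes

The acceptance suite checks, at sizes chosen to run in minutes on one
CPU: exact agreement of exhaustive-permutation maxT with a
brute-force oracle at n = 6; closed-form agreement of the Step-1/2
statistics on randomized tables; family-wise error of the global-null
pairwise scan (n = 400, 30 SNPs, B = 500, 100 replicates per trait
kind) inside the exact binomial 95% band around 0.05; top-rank power
≥ 80% for a planted interaction (penetrance contrast 0.3, MAF 0.3,
n = 1000, 100 replicates); retention of an interaction and
suppression of a pure-main-effect pair under co-dominant adjustment
(mean shift 0.6 SD in the interaction cells, 0.5 SD per allele for
the main effect — strong enough that failures indicate defects, not
power limits); speedMAXT set-identity and savings over 50 datasets;
the QC fixpoint/cascade contract plus exact-HWE enumeration for all
n ≤ 50; and filter sanity against brute-force neighbor oracles.
`scripts/acceptance.py` recomputes the same quantities from scratch
at comparable sizes and writes them as JSON.

## Known limitations

Interactions above order two, family-aware association, dosage
genotypes and PLINK binary files are out of scope.  The IBD moment
estimator is uncorrected for finite-sample allele-frequency error.
The Relief filters apply to binary traits only (as the underlying
algorithms require).  Continuous Step-1/2 tests assume approximate
normality within cells; heavy-tailed traits inherit the t-test's
behavior, though the permutation layer keeps family-wise error
control exact in distribution regardless.
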