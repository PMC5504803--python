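# Methods

This note records the models, parameter choices, numerical details and known
limitations behind each stage of the pipeline. It documents what the code
does and why; every empirical claim here is one the test suite or the
acceptance script itself computes.

## Ingestion and processing

Raw spectral-count tables may contain fractional counts (shared-peptide
splitting upstream) and several isoform rows per gene. Processing
consolidates isoforms first — rows sharing a gene symbol are summed
column-wise — and then replaces every value by its ceiling ("rounded up to
the nearest whole integer"). The order matters because the ceiling of a sum
differs from the sum of ceilings; consolidate-then-ceiling is the default
and the CLI exposes `--integerize-first` for the other order. A gene symbol
mapped to two distinct numeric gene ids is treated as an annotation
conflict and raises, rather than silently merging unrelated genes. Proteins
without a gene id are kept through differential expression but excluded
from ranking-based and pathway stages, which require identifier-keyed
memberships.

## Differential expression

All runs of a line are treated as samples: with 3 biological × 3 technical
replicates the test is 9 vs 9. The rationale is statistical feasibility —
a 3-vs-3 exact rank-sum test cannot produce a two-sided p below 0.1, so
technical replicates must enter the test for sub-0.001 p-values to be
attainable; the conservative alternative (`collapse_technical=True`
averages technical runs into their biological replicate) is provided but
makes the 90%-confidence threshold unreachable for untied genes.

The Wilcoxon implementation uses the exact permutation null when both
samples are untied with at most 8 observations each, and the normal
approximation with tie correction and continuity correction otherwise —
spectral counts tie frequently, so the asymptotic path is the common one.
"Detected" means a nonzero count total within a line; a DEP with zero total
in one line is labeled malignant-only / non-malignant-only rather than
up/down. The fold-change zero rule (add 1 to both means when either is
zero) is applied conditionally, never globally.

## Overrepresentation and the resampling validation

The test is the one-sided hypergeometric upper tail (Fisher's exact,
"greater"). Annotation databases are flat category → member maps with a
declared background size N; projected databases may declare a class size K
larger than the enumerated membership, and the declared K wins. Observed
overlaps are capped at the declared K.

The resampling validation draws `n_iter` (default 1000) subsets of the DEP
count uniformly without replacement from a pool (non-differential proteins,
or all identified proteins), runs the full per-category battery with BH
adjustment on each subset, and counts subsets in which a category is
significant. The per-subset significance threshold is BH q < 0.05
(`alpha`); the source analysis does not state its threshold, so this is the
package's definition, exposed as a parameter. One RNG stream per validation
run makes results bit-reproducible from the seed.

A caveat recorded as a limitation: published PANTHER-style p-values for
class overrepresentation are not reproducible from the printed (N, K, n, k)
via a plain hypergeometric tail — the web tool's effective background and
sample conditioning are not documented — so the package implements the
documented test and treats external tables' p/q columns as out of scope.

## Gene-set enrichment

The default ranking metric is signal-to-noise with the conventional
standard-deviation floor σ ← max(σ, 0.2·|μ|), and σ ← 0.2 when μ = 0 (a
constant-zero gene would otherwise divide by zero); `difference_of_means`
is available for designs too small to estimate variances. Ties in scores
are broken lexicographically by gene identifier, making ranks — and hence
every downstream quantity — deterministic.

The enrichment score is computed in closed form from the sorted hit
positions: the running sum is piecewise linear between hits, so its
positive extremum can only occur immediately after a hit and its negative
extremum immediately before one. On an exact tie of magnitudes the positive
extremum is preferred. Sets whose members cover every ranked gene have no
misses and are skipped with a warning.

The permutation null defaults to random equal-size gene sets rather than
phenotype relabeling: with three biological replicates per class there are
too few distinct phenotype permutations for a useful null
(`permutation_scheme="phenotype"` exists regardless). Nominal p uses the
same-signed null with the (count+1)/(n+1) estimator; NES divides ES by the
mean magnitude of same-signed null scores; FDR q is the pooled-null tail
ratio (fraction of all null NES at least as extreme, over the fraction of
observed NES at least as extreme, capped at 1). Effective set size — the
overlap with the measured genes — drives the [5, 500] size filter, both
bounds inclusive.

## Pathway impact

Topologies are signed gene × gene matrices assembled from edge lists with a
relation-type → weight map (activation/expression +1,
inhibition/repression −1, binding/association 0 by default; overridable).
Duplicate edges sum with a warning. The propagation system
(I − B)·PF = ΔE, with B the column-normalized signed adjacency, is solved
by LU factorization; the factorization is reused across all bootstrap
rounds of a pathway, so the bootstrap costs one matrix-vector solve per
round. If the system is singular (a feedback loop with unit gain), β is
damped by 0.99 per retry, logged, up to 20 times before erroring.

pPERT reassigns the observed ΔE magnitudes to uniformly drawn pathway
positions, median-centers the null, takes the (count+1)/(n_boot+1) tail in
the observed direction, doubles it to make it two-sided, and caps at 1 — an
observation at the null median thus gets p ≈ 1. Default n_boot = 2000.
pNDE conditions on measured genes (the background is the number of
identified genes with ids, not the genome). pG = c − c·ln(c) combines the
two; pathways with no DE genes carry no perturbation evidence and are
skipped. Calibration under a null in which the DE hit count is drawn from
its true hypergeometric distribution shows pG close to uniform; residual
deviation (Kolmogorov–Smirnov D around 0.08 at 500 simulations) is
intrinsic discreteness of the hypergeometric component, which the
calibration test's D ≤ 0.12 bound accommodates.

## Cohort comparison

"Stage-matched" is operationalized as identical Gleason group; matching is
greedy — within each Gleason stratum, repeatedly take the closest-aged
cross-race pair within the tolerance (default 5 years), each specimen used
once. Greedy matching is the package's definition; published cohorts rarely
document their pairing rule. The race test is Welch's unequal-variance t
(the common statistical default), with a pooled-variance option; zero
variance in both groups with equal means returns p = 1 by convention. No
multiple-testing correction is applied across the handful of genes tested,
matching raw-p reporting conventions; callers can BH-adjust the returned
column. Race-matched normalization subtracts, per gene, the arithmetic mean
over that race's non-malignant specimens from each tumor of the same race;
it is exact arithmetic and location-invariant within race.

## Synthetic data

The generators' defaults are the study conditions the pipeline targets:
833 genes, 3 biological × 3 technical replicates per line, 7.6% truly
changed genes (73% of them upward), |log₂ effect| = 2 (observed fold
changes in such designs cluster near ±2), 30% of changed genes zeroed in
the unshifted line to create one-line-only detections, a 20,814-gene
reference background with the curated protein-class size catalogue, and a
12 + 12 matched-pair tumor cohort with a 4 / 30 non-malignant reference
imbalance.

Counts are negative binomial (var = μ + φμ², default φ = 0.3 — spectral
counts are overdispersed) around gene-specific log-normal baselines
(median ≈ 10 counts), with a log-normal biological-replicate random effect
(σ = 0.15) shared by that replicate's technical runs — this creates the
nested correlation the 9-vs-9 testing decision must tolerate. Pathway
generators draw independent signed edges and always plant one multi-step
activating cascade so propagation has a route. Cohort expression is
Gaussian with additive race, disease and race × disease terms; ages are
drawn in cross-race pairs and Gleason scores alternate so matching is
feasible by construction.

What the generators do *not* emulate: peptide-level structure, shared
peptides, abundance-dependent detection efficiency, batch effects, and
real annotation dependence between categories. Passing tests therefore
demonstrate correctness and calibration of the statistics under the stated
stochastic model, not robustness to every artifact of real
mass-spectrometry data.

## Problem sizes in the test suite

The calibration tests use 200 null count datasets of 300 genes (FDR
control), 500 pathway null simulations of 60 genes with 200 bootstrap
rounds (pG uniformity), and six null datasets × 50 random sets × 500
permutations (GSEA nominal-p calibration); these sizes give Monte-Carlo
standard errors comfortably inside the asserted bounds while keeping the
default suite fast.

## Known limitations

- Published class-overrepresentation p-values from web annotation tools are
  not reproducible from printed marginals (see above); only the documented
  hypergeometric is implemented.
- The exact ranking metric and permutation scheme behind published GSEA
  tables, and their gene-set releases, vary; results are comparable in
  structure, not numerically.
- The impact analysis follows the perturbation-accumulation formulation
  with its standard defaults; KGML parsing is out of scope (edge-list TSVs
  are the topology interface).
- Greedy age matching is not optimal matching; with adversarial age
  distributions it can leave matchable specimens unmatched.
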