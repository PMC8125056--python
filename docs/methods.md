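# Methods

This note documents the statistical procedures `otunet` implements, the
generator's model and calibration, the numerical conventions, and the design
choices made where more than one defensible reading existed.

## The analysis pipeline

The pipeline takes an integer sample × OTU count table, per-sample host
metadata (species, feeding habit, diet-type group) and a host phylogeny, and
runs two branches from a single rarefied table:

1. **Diversity branch** — rarefied counts → alpha diversity + permutation
   t-tests; Bray-Curtis → PCoA, PERMANOVA, UPGMA; Mantel tests of Bray-Curtis
   against diet and host-phylogeny distances.
2. **Network branch** — rarefied counts → relative abundances → 0.01%
   mean-abundance filter → Spearman/BH network → pruning → subcommunities →
   per-sample SC statistics → Wilcoxon group comparisons.

All randomness flows from one master seed, expanded per stage with
`numpy.random.SeedSequence` and recorded in the run report.

### Rarefaction

Each sample is subsampled once, without replacement, to a common depth
(default 5,000 counts), by drawing read positions uniformly from the sample's
read multiset; the rarefied row therefore follows the multivariate
hypergeometric distribution and sums exactly to the depth. Samples with fewer
total counts than the depth are dropped and logged, not padded. A single draw
(rather than an average over repeats) keeps the downstream table an honest
integer count table; the seed is a required parameter.

### Alpha diversity

* **Chao1**: bias-corrected by default, `S_obs + F1(F1−1)/(2(F2+1))`, which
  stays finite when no doubletons exist; the classic `S_obs + F1²/(2F2)` is a
  flag. Integer counts are required — the estimator is undefined on fractions.
* **Shannon**: natural log by default with a base argument (base 2 available);
  the upstream convention is not standardised, so the base is explicit.
* **Faith's PD**: rooted convention — the stem path to the root is included —
  computed by walking each observed tip to the root and summing each branch
  once. Observed ids absent from the tree are dropped with a logged count
  rather than raising, because reference trees and OTU tables routinely
  disagree on a few names. (The computation is authored here rather than
  delegated: the library routine available in this stack rejects trees whose
  root is a polytomy, which valid inputs can have.)

### Permutation inference

PERMANOVA, the Mantel test and the alpha-diversity t-test share one
convention: the observed statistic is compared to label permutations, and
`p = (#{stat_perm ≥ stat_obs} + 1)/(B + 1)`. Ties count as hits (`≥` with a
1e-12 slack), so p is never zero and the minimum attainable value is
`1/(B+1)`. Each test also has an `exhaustive=True` mode enumerating all
distinct label arrangements (feasible for n ≲ 7–8), where
`p = #{stat_perm ≥ stat_obs}/N` with the identity included; the Monte-Carlo
and exhaustive routes are checked against each other in the tests.

* **PERMANOVA** uses Anderson's partition: `SS_total = Σ_{i<j} d²_ij / n`,
  `SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g`, pseudo-F
  `((SS_T−SS_W)/(a−1)) / (SS_W/(n−a))`, `r² = SS_between/SS_total`.
  Permutation is unrestricted (no strata), matching a single-factor design.
* **Mantel** correlates strictly-lower-triangle entries (Pearson by default,
  Spearman by flag); the null permutes one matrix's rows and columns jointly;
  p is one-sided (greater). Diet enters as Euclidean distance between one-hot
  group encodings; phylogeny as species-level patristic distance expanded to
  samples (zero within species). Both predictors are exposed; neither is
  hardcoded as canonical, since either convention appears in practice.
* **The alpha-diversity test** permutes group labels of the pooled values and
  compares |Welch t|, two-sided.

### PCoA and UPGMA

PCoA eigendecomposes `−½ J D² J` (J the centering projector). Axes are
ordered by descending eigenvalue; negative eigenvalues (non-Euclidean input)
are reported and logged but excluded from the variance denominators; no
Lingoes/Cailliez correction is applied by default. On Euclidean input the
embedding reproduces the distances to 1e-9 (tested).

UPGMA merges the closest pair of clusters at height d/2 with
size-weighted average linkage, so the dendrogram is exactly ultrametric
(equal leaf depths, tested to 1e-12). Ties are broken deterministically by
the lexicographically smallest member id of the candidate pairs. Output is a
standard tree object, written as newick.

### Co-occurrence network

* **Filter**: "relative abundance < 0.01%" is read as *mean* relative
  abundance across samples (a max-across-samples criterion is a flag). The
  surviving columns keep whole-community fractions — they are not
  renormalised — because the SC richness statistic is defined on
  whole-community relative abundances.
* **Correlation**: Spearman ρ as Pearson correlation of midranks, computed
  for all pairs at once; p-values from the t approximation
  `t = ρ√((n−2)/(1−ρ²))`, df = n−2, adequate at the pipeline's target sample
  sizes (n ≈ 100+). Constant profiles get ρ = 0, p = 1, logged. BH adjustment
  treats the n(n−1)/2 distinct pairs as one family (not per-OTU rows).
* **Edges**: `|ρ| ≥ 0.6` (inclusive) and BH-adjusted `p < 0.01` (strict),
  signed by the sign of ρ.
* **Pruning**: connected components with fewer than 4 nodes are removed; a
  component that small is necessarily a path or a cycle, so one size rule
  covers both shapes.
* **Subcommunities**: the default is connected components of the pruned
  graph, labelled a, b, c, … by descending size (ties by smallest member id).
  Visual delineation of subnetworks in a force-directed layout is not a
  reproducible computation; components are the closest deterministic
  equivalent, with greedy modularity refinement available for a single giant
  component. The number of SCs is an output, not a promise: an
  anti-correlated block pair, for instance, is joined by its negative edges
  into one component.
* **SC statistics**: per sample and SC, completeness
  `100 × |{members with abundance > 0}| / |SC|` (the presence threshold is an
  argument) and richness `Σ member fractions`. Group comparisons use
  two-sided Wilcoxon rank-sum tests — exact when both groups have ≤ 8
  tie-free observations, otherwise the tie-corrected normal approximation
  with continuity correction — BH-adjusted over the entire
  (group pair × SC × metric) family.

Note: BH adjustment is *not* idempotent (re-adjusting adjusted values
inflates them); adjusted p-values must be computed once from raw p-values.

## The generator

`simulate_dataset` draws, per seed:

1. a coalescent host tree (`n_species`, default 41) whose leaves are assigned
   round-robin to the seven diet groups; samples (default 128) are split
   near-equally across groups and cycled over their group's species;
2. per-OTU baseline log-abundances: background OTUs ~ Normal(0, 1.0);
   planted sets are *common taxa* — block members and diet-responsive OTUs
   ~ Normal(2.5, 0.5), phylogeny-tracking OTUs ~ Normal(1.5, 1.5) — because
   the OTUs that survive an abundance filter and drive community contrasts
   in real data are the dominant ones;
3. latent structure on log-abundances: per sample, each of the 6 blocks
   (20 OTUs each) has a standard-normal factor; a block member's
   log-abundance adds `latent_sd·(√ρ·z_block + √(1−ρ)·ε)` with ρ = 0.8 and
   `latent_sd` = 2.5 log units, giving within-block correlation ρ; one
   designated pair (blocks 0 and 3) shares a negated factor, giving latent
   correlation −ρ; each block's factor is additionally shifted by
   `block_group_affinity` (default 1.0) in one diet group, so SC completeness
   and abundance genuinely differ between groups;
4. diet effects: 8 OTUs per group get a +2.0 log-fold shift in their group
   (no study reports an effect-size scale; these are detectability-motivated
   defaults and are labelled as such);
5. a host-phylogeny effect: each of 60 designated OTUs follows its own
   independent Brownian-motion realization on the host tree (covariance =
   shared root path length, normalised to unit scale, per-OTU sd 1.5 log
   units). Independent per-OTU draws — rather than one shared factor — both
   match how separate traits evolve and keep the aggregate phylogenetic
   signal stable across seeds;
6. sequencing depths ~ log-normal with mean 51,768 and SD 18,927 tags;
7. counts ~ Multinomial(depth, softmax(log-abundances)) per sample, so the
   compositional coupling real relative abundances carry is present.

**Sparsity calibration.** The target is that 90% of OTUs occur in fewer than
20% of samples. The dial is a scalar *downward shift* of the background
baselines only; the expected sparsity is computed analytically (per-sample
detection probability `1 − exp(−depth·p)`) over *detectable* OTUs — mirroring
a real table, which only contains OTUs observed somewhere. Because an extreme
shift removes OTUs from the detectable set entirely, the objective is
non-monotone, so the shift is found by a coarse grid with local refinement
rather than bisection, and logged. A multiplicative temperature on all
baselines was rejected: it cannot reach the target without letting a few
background OTUs swallow the simplex and destroy the planted structure.

**What the generator does not emulate.** Taxonomy is synthetic labels;
there is no sequencing error, chimera structure or batch effect; depth and
composition are independent; diet groups are balanced, unlike most field
studies; the planted correlation is block-constant rather than scale-free.
Passing recovery tests therefore demonstrates that the *pipeline* detects the
structure it targets under a realistic abundance/sparsity regime — not that
any particular biological dataset contains such structure.

## Problem sizes used by the tests and acceptance script

Unit tests run on hand-sized instances and a 24-sample × 60-OTU tiny design.
Calibration uses 500 replicates of a 24 × 40 null design with 99-permutation
tests; block recovery uses 50 replicates of 100 samples × 60 OTUs (3 planted
blocks of 15, ρ = 0.8); the study-scale run is 128 × 2,400 with depth-5,000
rarefaction, 999 PERMANOVA and 9,999 Mantel permutations. The full suite
finishes in well under a minute on one CPU; the acceptance script in ~10 s.
The rarefaction moment check uses totals [200, 50] at depth 50 over 2,000
draws against the closed-form hypergeometric mean and variance.

## Known limitations

* Spearman on relative abundances is compositionally naive by design — the
  procedure implemented is the plain-correlation network, not SparCC-style
  compositionally-aware inference; the generator's multinomial sampling means
  this caveat applies to the synthetic data exactly as to real data.
* The Spearman p-values use the t approximation; an exact permutation option
  exists only pairwise and is impractical for full matrices.
* PERMANOVA is single-factor, unrestricted permutation; no strata or
  covariate adjustment.
* `n_subcommunities` depends on the component structure of a thresholded
  graph and is sensitive to the ρ cutoff near attenuated block correlations.
* GraphML round-trips convert absent SC labels to empty strings (GraphML
  cannot represent null attributes).
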