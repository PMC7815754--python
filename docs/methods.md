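# Methods

`guteco` infers the ecological processes governing the succession of
host-associated microbial communities — selection, dispersal and drift — from
OTU tables, a reference phylogeny and per-sample metadata, and ships a
synthetic metacommunity generator that emulates a hatch/transition rearing
experiment so every stage of the inference can be verified without real
sequencing data.

## The inference stack

### Phylogenetic turnover: βMNTD and βNTI

For a pair of communities with relative abundances *x*, *y* and cophenetic
distances *d*, the abundance-weighted beta mean nearest taxon distance is

    βMNTD(x, y) = ½ [ Σᵢ xᵢ · min_{j∈y} d(i,j)  +  Σⱼ yⱼ · min_{i∈x} d(i,j) ]

with sums over taxa present in each community (shared taxa contribute zero).
βNTI is the z-score of the observed βMNTD against a null that shuffles tip
labels across the whole phylogeny (equivalently, jointly permutes rows and
columns of the cophenetic matrix) while holding abundances fixed. The shuffle
universe is every OTU of the input table — the whole-study tree — not only
the taxa detected in the habitat under analysis. The permutation sequence is
derived from the global seed and shared across all pairs, and the internal
taxon order is canonicalised by sorted OTU id, so results are invariant to
input ordering. Pairs whose two communities share their entire support have
a constant null (βMNTD ≡ 0 under every shuffle) and are assigned βNTI = 0;
the pairwise operation raises an error instead when the null variance is
zero but the observed value differs (e.g. a star tree).

### Compositional turnover: Raup–Crick on Bray–Curtis

Each null replicate assembles both communities of a pair from the
metacommunity table: observed richness is held fixed, species are drawn
without replacement with probability proportional to occupancy frequency
(Gumbel top-k sampling), one read seeds each drawn species, and the remaining
reads are allocated multinomially with probability proportional to
metacommunity relative abundance. RC_bray is twice the tie-half-weighted
fraction of null Bray–Curtis values below the observed one, minus one, hence
lies in [−1, 1]. Because rarefied samples share a common depth, observed and
null Bray–Curtis values are compared as exact integer numerators, so ties are
detected exactly. Each pair draws from a random stream derived from
(seed, canonical pair id); results do not depend on iteration order.

### Five-way process classification

Selection rules are applied first: βNTI > +2 → heterogeneous selection,
βNTI < −2 → homogeneous selection. Only when |βNTI| < 2 do the dispersal
rules apply: RC_bray > 0.95 → dispersal limitation, RC_bray < −0.95 →
homogenizing dispersal; anything else is undominated (weak selection, weak
dispersal, diversification, drift). Thresholds and replicate count (default
999) are configurable. Within-stage gut sample pairs, pooled across tanks
and cages, form the default pairing universe; a `within="cage"` option
restricts pairs to a shared metadata level.

### Selection strength (α/γ-constrained null)

For a group of samples (a developmental stage), observed mean within-group
Bray–Curtis similarity S_obs = 1 − mean(BC) is compared with null replicate
means in which every group sample is re-assembled by the Raup–Crick null
above — holding per-sample α-diversity fixed and drawing from the γ pool of
the whole table. The deterministic ratio is (S_obs − S̄_null)/S_obs, clipped
to [0, 1]; the p-value is the (+1-corrected) fraction of null replicate
means at or above S_obs. The normalisation of this ratio is genuinely
ambiguous in the literature this procedure descends from; the implemented
form is one defensible reading, isolated behind a single function, and an
alternative dissimilarity-scale ratio (D̄_null − D_obs)/D̄_null is available
via `ratio_scale="dissimilarity"`.

### Rao diversity partition

Rao quadratic entropy Q = Σᵢⱼ pᵢ pⱼ dᵢⱼ is computed with the species-neutral
dissimilarity dᵢⱼ = 1(i≠j) by default (then Q is the Gini–Simpson index); a
phylogenetic dissimilarity can be supplied instead. Ecosystem diversity is
decomposed as γ = α_local + β_intra-habitat + β_inter-habitat, where habitats
(water vs gut) contribute with equal weight regardless of sample counts and
pooled communities are unweighted means of their members' relative-abundance
vectors. With the default equivalent-numbers correction, the *mean raw Q of
each level* is transformed to 1/(1−Q) before differencing. Transforming
level means (rather than transforming each sample's Q and then averaging)
is what guarantees non-negative β components: Q is concave under pooling for
both supported dissimilarities, so each level's pooled Q dominates its mean
member Q, and the monotone transform preserves the ordering. Additivity of
the three components is exact by construction on either scale.

### Community statistics

* **PERMANOVA**: SS_total = Σ_{i<j} d²ᵢⱼ/n, within-group sums analogously;
  pseudo-F = [SS_between/(g−1)]/[SS_within/(n−g)]; p by unrestricted label
  permutations with the +1 correction (never exactly zero), or exact
  enumeration of all distinct assignments for small designs.
* **Mantel / partial Mantel**: Pearson correlation over the n(n−1)/2
  off-diagonal pairs; one-sided permutation p (ecology convention,
  positive association), permuting one matrix's ids; the partial statistic
  r(AB.C) = (r_AB − r_AC·r_BC)/√[(1−r²_AC)(1−r²_BC)] with permutations on A.
  When the control equals one of the matrices the statistic is 0 by
  construction (0/0 limit handled explicitly).
* **ANOVA + LSD**: one-way F, then pairwise least-significant-difference
  t-tests on the pooled mean square error — deliberately unadjusted for
  multiplicity, which is what LSD is — summarised as a compact letter
  display built from maximal cliques of the not-significantly-different
  graph.
* **Hierarchical partitioning** (Chevan–Sutherland): a factor's independent
  contribution is the average, stratified by subset size, of its R² gain
  over all subsets of the remaining factors; independent contributions sum
  exactly to the full-model R². Factors are dummy-coded categoricals fit by
  ordinary least squares; aliased factors raise an error.

## The synthetic metacommunity generator

The generator emulates a rearing experiment in which sibling fish hatch in
three water environments (A, B, C), are transferred at the first sampled
timepoint into net cages inside three tanks (one tank per environment, one
cage per hatching environment — cages with hatch = rear environment are the
"original" cages), and are sampled with three replicate fish per cage at
seven timepoints (12, 20, 27, 42, 56, 70, 98 days post-hatching) spanning
three developmental stages (12–20, 27–42, 56–98 dph). Water is sampled in
triplicate at every timepoint except the second. The default design thus
yields 189 gut and 54 water samples. Food is a deterministic function of age
(live feed before 20 dph, dry food after), hence partially confounded with
stage exactly as in the real design — documented, not "fixed".

Key components, with defaults and why:

* **Phylogeny** — two-level pure-birth tree, unit depth: a backbone of
  ~`cluster_fraction`·n lineages (default 0.25) whose split times are pulled
  toward the root (accelerating-rate profile), each radiating into a small
  terminal cluster of depth `cluster_depth` (default 0.02). This reproduces
  the strongly bimodal distance structure of real 16S trees (tiny
  within-genus distances, long between-clade paths), which is what gives
  nearest-taxon statistics their dynamic range. A constant-rate Yule tree is
  available (`cluster_fraction=None`) but has nearly uniform nearest-
  neighbour distances and little βNTI contrast.
* **Trait** — Brownian motion along the tree (rate 1.0). On the clustered
  tree most trait variance falls on the deep backbone, so close relatives
  share trait values: the phylogenetic signal that lets a trait filter
  produce phylogenetically clustered communities.
* **Species pools** — the OTU universe is partitioned into
  environment-unique (63.7% in total, split equally), pairwise-shared (8%
  per pair) and triple-shared regions, matching the emulated study's Venn
  structure; log-normal abundances (σ = 1.0) are drawn once and shared
  across environments. Taxa with high host affinity (trait near any stage
  optimum) are preferentially placed in the triple-shared region
  (`host_affinity_bias`), reflecting the observation that successful gut
  colonisers tend to be present, at low abundance, in every environment.
* **Water communities** — the environment pool with log-normal temporal
  jitter (σ = 0.3) per timepoint.
* **Gut communities** — a per-cage latent community evolves across
  timepoints: each step mixes immigrants from the source water (fraction
  `dispersal_rate`, default 0.25; the hatching environment's water at the
  first timepoint, the rearing tank's water afterwards), applies log-normal
  cage drift (σ = 0.4), and filters by the stage's Gaussian trait filter
  p ∝ pool·[(1−s) + s·exp(−(trait−optimum)²/2σ²)] with σ = 0.35 trait-SD
  units and stage optima at the 0.2/0.5/0.8 trait quantiles (quantile
  placement guarantees every stage's niche sits in an occupied region of
  the trait distribution). Replicate fish are independent multinomial draws
  of `depth` reads (drift). Selection therefore *compounds* across
  development — a single filter application is bounded by the (1−s) floor
  of the mixture, but the succession of filter steps, punctuated by
  immigration, concentrates late-stage communities on the selected clades
  the way cumulative host selection does. This is what makes the default
  schedule s = (0.3, 0.6, 0.8) recoverable as a stage-increasing
  homogeneous-selection fraction.
* **Regimes** — `dispersal_rate` near 1 with a single shared pool gives
  homogenizing dispersal; `cage_pool_frac` < 1 (per-cage random pool
  restriction) with low dispersal gives dispersal limitation; s = 0
  everywhere gives neutral truth.

All randomness derives from named child streams of one seed
(`(seed, stream-name, entity-id)`), so identical configurations are
bit-identical, results are independent of iteration order, and adding a
consumer never perturbs existing streams.

### What the generator does not emulate

Sequencing error, chimeras and compositional artefacts; mechanistic gut
physiology or immune dynamics; taxon-taxon interactions; seasonal or diel
water dynamics beyond log-normal jitter. Passing tests therefore show that
the inference machinery recovers known generating regimes under a clean
read-generation model, not that it is robust to the full error structure of
real amplicon data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: reduced studies use an
800-OTU universe, 54 gut + 45 water samples (six timepoints, one or two
replicate fish), 500 reads per sample and 199 null replicates; the
full-design checks (189 + 54 samples, depth 14,666) run the generator and
diversity stack only. The βNTI universe must be several times larger than
per-sample richness for the taxa-shuffle null to have dynamic range — at a
200-OTU universe the null collapses regardless of the true regime, which is
why the reduced configurations keep ≥800 OTUs while shrinking sample counts
and depth instead. Null z-scores use float32 distance gathers in the batch
path (the per-pair reference path is float64 and matches a naive oracle to
1e-12). Permutation p-values always carry the +1 correction. Rarefaction is
multivariate-hypergeometric (without replacement), per-sample streams, and
drops samples below depth rather than padding.

## Known limitations

* The selection-strength deterministic ratio discriminates weakly at strong
  selection in this generator: the (1−s)-floored single-draw filter and the
  high stochasticity of the α/γ-preserving null bound the achievable ratio
  near 0.2–0.25 under configurations where the neutral regime is correctly
  calibrated (observed ≈ null). The neutral calibration is verified by test;
  the strong-selection ratio threshold of 0.3 is not reliably exceeded and
  the corresponding check is expected to fail under honest conditions.
* Water–gut habitat contrast in the partition is driven entirely by the
  trait filter and pool structure; no gut-specific taxa exist outside the
  water pools, so β_inter-habitat is smaller than in systems with truly
  host-restricted taxa.
* PERMANOVA permutations are unrestricted; a strata option for cage-nested
  designs is not implemented.
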