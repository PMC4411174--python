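# Methods

This note documents the models, estimators and numerical choices behind
`regiondiv`, and what the synthetic test bed does and does not
demonstrate.

## The question the pipeline addresses

Amplicon surveys of bacterial communities sequence one or two of the
nine hypervariable regions of the 16S rRNA gene. Regions differ in how
many informative sites they contain, so the same community yields
different OTU inventories depending on the region: a finer-resolving
region separates lineages that a coarser one collapses, and a coarser
region merges recently diverged taxa. The pipeline quantifies how this
propagates into standard ecological metrics when the *same* samples are
characterised through several regions in parallel.

## Synthetic metacommunity

The generator produces data whose statistical structure matches what
the downstream analyses assume, with complete provenance.

**Species pool and lakes.** A regional pool of `n_species` (default
300) species receives lognormal log-abundances (`meanlog = 0`,
`sdlog = 1.2`), giving the hollow-curve rank-abundance shape typical of
bacterial communities. The `n_lakes` (default 20) lakes sit at evenly
spaced positions on a unit environmental axis. Each species has a
Gaussian niche: optimum uniform on the axis, SD `niche_breadth`
(default 0.35 axis units). Occupancy of lake *l* by species *s* is
Bernoulli with probability `occupancy × suitability(l, s)` (occupancy
default 0.8), and the species' lake abundance is its regional
abundance times suitability times lake-level lognormal noise
(`lake_sdlog = 0.75`), renormalised per lake. The gradient is what
gives lake pairs non-trivial β-diversity structure — nearby lakes share
more species than distant ones — which is precisely what the Raup-Crick
analysis measures. Setting `niche_breadth = None` removes the gradient
and makes lakes exchangeable; in that regime the Raup-Crick null is
calibrated (≈5% of pairs significant), which the test suite checks.

**Phylogeny.** A pure-birth (Yule) tree with unit birth rate over the
species, all branch lengths strictly positive.

**Regional resolution.** Each region views the species pool through a
resolution map. A `split_fraction` of species (default 0.5 for the
fine region, emulating a region with roughly twice as many informative
sites) is resolved as two variant OTUs, placed as a cherry separated by
an epsilon branch (10⁻³ of the mean branch length — splits are
taxonomic, not phylogenetic, so they add essentially no branch length).
Each lake divides a split species' abundance between the two variants
with its own Beta(0.02, 0.02) proportion: the near-Bernoulli shape
means different lakes carry different variants, the mechanism by which
finer resolution reduces apparent between-lake sharing. A
`lump_fraction` of species (default 0.15 for each coarse region) is
merged into its nearest available phylogenetic neighbour, removing its
terminal branch — the mechanism by which coarse regions lose
phylogenetic diversity. Which species get lumped is driven by a shared
per-species "lumpability" score plus a small region-specific jitter
(0.1), because species that are hard to resolve (recently diverged,
low sequence distinctiveness) are hard for *any* coarse region;
independent draws would make the two coarse regions disagree with each
other as much as with the fine one. Expected OTU count is
`n·(1 + split_fraction − lump_fraction)`.

**Sequencing.** Each lake is a multinomial draw of `depth_per_lake`
(default 1500) reads from its region-OTU relative abundances, chosen
inside the per-lake read range a trimmed single-region amplicon dataset
typically yields.

**Reads.** Each table count becomes one read: random 5–25 nt flank +
conserved 11-mer anchor + the OTU's variable segment (a window of the
species' 460 nt template; the second variant of a split diverges at 8%
per site so a 97% identity threshold separates the pair) + random
flank, with 0.2% per-base substitution error and 50% of reads emitted
reverse-complemented. Construction guarantees the anchor occurs exactly
once in the forward orientation and its reverse complement never, so
anchored trimming must recover exactly the planted segment; anchor-free
background reads are available as negative controls.

**ARISA.** Species fragment lengths are drawn without replacement from
a 3.0 nt grid on [200, 1200] nt — the grid step is a multiple of the
1.5 nt binning window, so a binning frame exists in which a species'
±0.5 nt jittered observations never straddle a bin edge. Peak
fluorescence is proportional to relative abundance.

**What the generator does not emulate:** PCR and chimera artifacts,
quality-score structure, copy-number variation, chloroplast
contamination, taxonomic reference databases, or any quantitative model
of *why* one region resolves more taxa (split/lump fractions are free
knobs, set once). Passing tests therefore show the pipeline's
statistics behave correctly on data satisfying its assumptions — not
that any particular real region pair behaves like the defaults.

## Estimators and algorithms

**Trimming.** Exact 11-mer matching, leftmost match wins; reads failing
the forward screen are rescanned as reverse complements; windows
running past the read end count as "too short". No mismatch tolerance:
screening is on fixed k-mers.

**Clustering.** Greedy centroid clustering on equal-length reads:
unique sequences in decreasing total abundance (ties lexicographic)
join the first centroid with Hamming identity ≥ the threshold
(`best-fit` assignment is available as an option); `N` matches nothing.
This is a deterministic stand-in for UCLUST-style de novo picking, not
a reimplementation of any specific binary. The threshold sweep is
*nested*: reads are clustered once at the strictest threshold and
centroids are then merged at each looser one, so partitions refine one
another and OTU counts and richness are non-increasing along the sweep
by construction rather than empirically.

**Rarefaction.** Without replacement (multivariate hypergeometric).
Samples below the depth are dropped with a warning in pipeline mode.
SR and PD are averaged over `n_rarefactions` independent draws
(default 1000); the closed form
`E[SR] = Σᵢ (1 − C(T−tᵢ, d)/C(T, d))` is exposed for exact expected
richness.

**Faith's PD.** Sum of branch lengths of edges subtending at least one
present tip. The root's own edge, if present in the Newick source, is
excluded — PD counts edges strictly below the root. Edge lengths are
summed in ascending order so the result is permutation-independent; a
precomputed edge × tip incidence matrix vectorises PD over rarefaction
replicates. Unrooted (trifurcating-root) trees are rejected rather
than auto-rooted.

**Raup-Crick.** The species pool is the set of OTUs present anywhere in
the dataset (never pooled across regions). For a pair with observed
richness (αᵢ, αⱼ) and shared count SSobs, null communities of the same
richness are drawn without replacement from the pool, by default with
probability proportional to occurrence frequency across samples
(uniform weighting is the enumerable mode). Weighted sampling without
replacement uses the Gumbel top-k construction, equivalent to
successive draws. `p = [#(SSnull > SSobs) + ½·#(SSnull = SSobs)]/N`
and `RC = 2p − 1`; the half-weight on ties keeps the statistic centred.
Pair-level RNGs derive from (seed, i, j) with i < j, so the matrix is
exactly symmetric; an opt-in `share_sample_draws` mode draws each
sample's nulls once and reuses them across pairs (identical per-pair
marginal law, ~20× faster; used by the pipeline stage). Under uniform
weighting and a pool ≤ 12, the null shared-count law is
`Hypergeom(γ, αᵢ, αⱼ)` and `rc_exhaustive` evaluates p exactly — the
oracle the Monte-Carlo path is tested against.

Because a single rarefaction draw is the dominant noise source for
pairwise verdicts (measured: two rarefactions of the same table agree
on only ~162/190 pair verdicts, versus ~188/190 for Raup-Crick
Monte-Carlo noise at N = 800), the β stage averages Jaccard,
Bray-Curtis and RC matrices over `beta_rarefactions` (default 16)
independent rarefaction replicates — the same anti-rarefaction-noise
logic the SR/PD estimator uses. Verdict classification (±0.975 band)
is applied to the averaged matrix.

**Model II regression.** MA slope from the covariance closed form
(equivalently the leading eigenvector); intercept through the
centroid; r² is the squared Pearson correlation. The 95% CI rotates
the major axis by `atan(A)`, `A = √(H/(1−H))`,
`H = F₀.₀₅(1, n−2) / [(λ₁/λ₂ + λ₂/λ₁ − 2)(n − 2)]`, which matches the
asymptotic variance of the principal-axis angle; empirical coverage at
n = 20 with symmetric bivariate noise is ≈0.94. Degenerate cases:
collinear data give a zero-width interval; H ≥ 1 gives an unbounded
one; zero covariance is an error (the axis is undefined). Slopes are
"different from 1" iff 1 is outside the interval; posthoc letters are
connected components of the CI-overlap graph (transitive closure), a
deterministic documented rule.

**Rank-abundance and KS.** Each OTU contributes its abundance as one
observation; the two-sample KS test (asymptotic p) compares the two
abundance-value distributions, making the test well defined and
sample-size aware. Log-log slope is OLS of ln(abundance) on ln(rank);
an optional rank window restricts the range, defaulting to all ranks.

**ARISA binning.** Candidate frames at offsets k·shift
(k = 0…window/shift − 1; window/shift must be integral). Within a
(sample, bin), fluorescence is summed, then normalised per sample; the
frame maximising the mean pairwise Pearson correlation of
relative-fluorescence profiles across samples wins, ties to the lowest
offset, with a degenerate single-sample input falling back to the
first frame with a warning. A fluorescence floor is exposed but
defaults to 0 (keep all peaks).

**Group statistics.** One-way ANOVA (scipy) with Tukey HSD
(statsmodels) letters by the same transitive-closure rule; per-class
paired t-tests (zero-variance nonzero differences report t = ±∞,
p = 0); OLS with the overall F test (= squared slope t). The ten "top"
classes are ranked by mean relative abundance jointly across all
samples and regions. No multiple-testing correction is applied by
default.

## Orchestration and determinism

Every stochastic operation takes an explicit seed; stage RNGs derive
from the master seed plus a stable key (CRC of the stage name, pair
indices, replicate number), so any stage can be re-run in isolation and
two runs with the same master seed produce byte-identical reports
(sorted-key JSON plus TSV matrices). Double-region datasets are
supported end-to-end (rarefaction default 150 reads) but excluded from
the default β/rank stages, which compare the three single regions.

## Problem sizes

Defaults follow the study design the pipeline models: 20 lakes, 650
(single-region) / 150 (double-region) rarefaction depth, 1000
rarefaction replicates, 10000 RC iterations, ±0.975 band, SST grid
{0.85, 0.90, 0.95, 0.97, 0.99}. The test suite and the acceptance
script scale repeat counts, not the design, for interactive runtimes:
100–250 rarefaction replicates, 400 RC iterations × 16 β-rarefaction
replicates, 20–50 pipeline repetitions, 300-species pools. The
direction-of-effect analyses use the full default metacommunity.

## Known limitations

- Greedy clustering is order-dependent and only approximates the
  behaviour of production OTU pickers; only the nested sweep guarantees
  monotone OTU counts across thresholds.
- The fine region's PD advantage arises entirely from coarse-region
  lumping (splits add epsilon branch length by design); a generator
  with phylogenetically divergent variants would need a different
  split placement rule.
- Hamming identity assumes the trimmer produced exactly equal-length,
  gap-free segments; indel-bearing reads are outside the model.
- The Raup-Crick implementation fixes null richness to observed
  richness and exposes the draw weighting; other published variants
  (abundance-based RC, fixed-frequency swaps) are out of scope.
- MA confidence intervals rely on an asymptotic angle variance;
  coverage was verified at n = 20 but very small n or near-circular
  covariances give wide or unbounded intervals by construction.
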