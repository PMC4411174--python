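# regiondiv

Estimates of bacterial diversity from amplicon sequencing depend on which
variable region of the 16S rRNA gene a study targets. `regiondiv` is a
pipeline for quantifying that dependence: it takes (or simulates) read
sets, OTU tables and phylogenies derived from different 16S regions (V3,
V4, V5, and the double regions V3-V4 / V4-V5) for the same set of
samples, and compares the ecological conclusions each region supports —
species richness, Faith's phylogenetic diversity, β-diversity,
rank-abundance structure, and agreement with ARISA fingerprinting.

It is aimed at microbial ecologists who want to know how robust a
diversity result is to the choice of marker region, and at method
developers who need a fully synthetic, provenance-tracked test bed for
amplicon diversity pipelines.

## What it computes

For each region dataset (samples × OTUs count table plus a rooted tree):

- **α-diversity** — species richness `SR` (number of OTUs with count
  > 0) and Faith's phylogenetic diversity
  `PD = Σ branch lengths of the rooted subtree spanning observed OTUs`,
  both averaged over repeated rarefaction (default 1000 draws without
  replacement to 650 reads), with one-way ANOVA + Tukey HSD letters
  across regions.
- **Model II regression** — major-axis fits between regions and between
  SR and PD. The MA slope is the first principal axis of the sample
  covariance, `b = (s_yy − s_xx + √((s_yy − s_xx)² + 4 s_xy²)) / (2 s_xy)`,
  with an F-based confidence interval obtained by rotating the axis;
  slopes whose CIs overlap share a posthoc letter.
- **β-diversity** — Jaccard (presence/absence), Bray-Curtis
  (abundance), and the modified Raup-Crick index: for each sample pair
  the observed shared-species count is compared against null
  communities reassembled from the dataset's species pool
  (γ-diversity) at the observed richness (default 10000 iterations);
  `RC = 2p − 1 ∈ [−1, 1]`, with ±0.975 marking pairs significantly more
  dissimilar (+) or more similar (−) than chance. Two regions' RC
  matrices are classified pair-by-pair into agreement categories
  a/b/c/d (same verdict / one significantly similar vs neutral / one
  significantly dissimilar vs neutral / opposite verdicts).
- **Rank-abundance** — per-lake and pooled rank-abundance
  distributions, two-sample Kolmogorov-Smirnov comparison between
  regions, and the log-log slope used in the clustering-threshold
  sweep.
- **OTU clustering sweep** — greedy centroid clustering of
  fixed-length trimmed reads at sequence-similarity thresholds
  0.99 → 0.85 (nested: centroids are merged as the threshold loosens),
  tracking how SR, PD, β-diversity and rank-abundance slopes respond.
- **ARISA** — fragment-length binning with a sliding binning frame
  (window 1.5 nt, shift 0.3 nt; the frame maximising mean pairwise
  Pearson correlation of relative fluorescence across samples is
  selected), richness extraction, and OLS regressions of sequencing SR
  against ARISA SR.

A read-level front end trims mixed-region reads into fixed-length
per-region subsets by exact conserved 11-mer anchor matching with a
reverse-complement rescan (V3/V4: 120 nt, V5: 100 nt, V3-V4: 360 nt,
V4-V5: 311 nt).

The `regiondiv.simulate` module generates a complete synthetic study —
a 20-lake metacommunity with lognormal abundances on an environmental
gradient, a pure-birth phylogeny, region-specific resolution maps (one
region resolving finer than the others), multinomially sequenced OTU
tables, anchor-planted reads, and jittered ARISA profiles — with full
provenance from every count back to a true species.

## Worked example

```
$ regiondiv demo --seed 1 --out demo-out
demo report written to demo-out/report.json
```

which runs the seeded synthetic 20-lake study (300 species, 1500 reads
per lake, V4 configured to resolve finer than V3/V5) and writes
`report.json` plus per-region Raup-Crick matrices. From that report
(seed 1):

| region | mean SR | mean PD | median Jaccard | RC pairs sig. similar |
|--------|--------:|--------:|---------------:|----------------------:|
| V3     |    99.2 |   147.9 |          0.696 |                  0.23 |
| V4     |   105.5 |   151.0 |          0.823 |                  0.13 |
| V5     |    99.0 |   148.0 |          0.703 |                  0.21 |

The finer-resolving V4 dataset reports the highest richness and
phylogenetic diversity and the most dissimilar communities — the same
qualitative pattern a real multi-region comparison shows — and the RC
agreement counts (category *a*: V3|V5 174 vs V3|V4 159, V4|V5 163 of
190 lake pairs) show the two coarse regions agreeing with each other
more often than either agrees with V4, so the choice of region, not
the community, drives the disagreement.

Python API equivalent:

```python
from regiondiv import PipelineConfig, run_pipeline
from regiondiv.simulate import TruthConfig

report = run_pipeline(PipelineConfig(truth=TruthConfig(seed=1), seed=1))
print(report["alpha"]["V4"]["summary"])
```

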