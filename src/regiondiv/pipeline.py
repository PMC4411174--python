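"""End-to-end orchestration of the region-comparison study.

Wires the stages together: synthetic (or loaded) per-region OTU tables
and trees -> repeated-rarefaction SR/PD -> model-II regressions between
regions -> Jaccard / Bray-Curtis / Raup-Crick beta diversity with the
RC agreement classification -> rank-abundance comparisons -> ARISA
binning and ARISA-vs-sequencing regressions -> class-level paired
t-tests.  Everything derives from one master seed; the report is a
plain dict serialised as deterministic JSON plus TSV matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist
from skbio import TreeNode

from .alpha import TreeIncidence, mean_rarefied_metric, rarefy
from .arisa import arisa_richness, bin_peaks
from .beta import (DissimilarityMatrix, RCConfig, bray_curtis_matrix,
                   compare_rc_matrices, jaccard_matrix, raup_crick)
from .cluster import greedy_cluster, merge_centroids
from .model2 import compare_slopes, ma_fit
from .rank import build_rank_abundance, ks_compare, loglog_slope
from .simulate import SyntheticDataset, TruthConfig, generate_dataset
from .stats import anova_tukey, linear_regression, paired_class_tests, top_classes
from .types import OTUTable

__all__ = ["PipelineConfig", "run_pipeline", "sst_sweep", "write_report",
           "demo", "class_abundance_table", "centroid_tree"]

DEFAULT_SST_GRID = (0.85, 0.90, 0.95, 0.97, 0.99)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end comparison, with the study defaults."""

    truth: TruthConfig = field(default_factory=TruthConfig)
    rarefaction_depth: int = 650        # single-region analyses
    double_region_depth: int = 150      # V3-V4 / V4-V5 analyses
    n_rarefactions: int = 1000
    beta_rarefactions: int = 16  # rarefaction replicates averaged for beta
    rc_iterations: int = 10000
    rc_weighting: str = "occurrence_frequency"
    significance_band: float = 0.975
    sst_grid: tuple = DEFAULT_SST_GRID
    ks_alpha: float = 0.05
    n_top_classes: int = 10
    seed: int = 0
    stages: tuple = ("alpha", "ma", "beta", "rank", "arisa", "classes")

    def __post_init__(self) -> None:
        for name, v in (("rarefaction_depth", self.rarefaction_depth),
                        ("n_rarefactions", self.n_rarefactions),
                        ("rc_iterations", self.rc_iterations)):
            if v < 1:
                raise ValueError(f"{name} must be positive")
        if any(not 0 < s <= 1 for s in self.sst_grid):
            raise ValueError("sst values must lie in (0, 1]")

    def parameters(self) -> dict:
        d = asdict(self)
        d["truth"]["region_specs"] = [asdict(s)
                                      for s in self.truth.region_specs]
        d["stages"] = list(self.stages)
        d["sst_grid"] = list(self.sst_grid)
        return d


def class_abundance_table(table: OTUTable, species_classes: dict[str, str]) -> pd.DataFrame:
    """Samples x classes relative abundances.

    Region-OTU ids map to their source species (``sp0001.a -> sp0001``)
    and species to class labels.
    """
    classes = sorted(set(species_classes.values()))
    pos = {c: j for j, c in enumerate(classes)}
    mat = np.zeros((table.n_samples, len(classes)))
    totals = table.sample_sums().astype(float)
    for j, otu in enumerate(table.otu_ids):
        sp = otu.split(".")[0]
        cls = species_classes[sp]
        mat[:, pos[cls]] += table.counts[:, j]
    mat /= np.maximum(totals[:, None], 1.0)
    return pd.DataFrame(mat, index=table.sample_ids, columns=classes)


def _fit_dict(fit) -> dict:
    return {"slope": fit.slope, "intercept": fit.intercept, "r2": fit.r2,
            "ci_low": fit.slope_ci[0], "ci_high": fit.slope_ci[1],
            "n": fit.n}


def run_pipeline(config: PipelineConfig,
                 dataset: SyntheticDataset | None = None) -> dict:
    """Run every requested stage and return the comparison report.

    When ``dataset`` is None a synthetic dataset is generated from
    ``config.truth`` (whose seed is taken from the pipeline seed).
    """
    if dataset is None:
        truth = config.truth
        truth.seed = config.seed
        dataset = generate_dataset(truth)
    regions = list(dataset.tables)
    report: dict = {"parameters": config.parameters(), "regions": regions}
    depth = config.rarefaction_depth

    def region_depth(region: str) -> int:
        # double-region datasets (V3-V4, V4-V5) carry fewer reads and
        # use their own shallower rarefaction depth
        return config.double_region_depth if "-" in region else depth

    alpha_sr: dict[str, dict[str, float]] = {}
    alpha_pd: dict[str, dict[str, float]] = {}
    if "alpha" in config.stages or "ma" in config.stages \
            or "arisa" in config.stages:
        alpha = {}
        for region in regions:
            table = dataset.tables[region]
            tree = dataset.region_trees[region]
            sr = mean_rarefied_metric(table, region_depth(region), "SR",
                                      n_replicates=config.n_rarefactions,
                                      seed=config.seed)
            pdv = mean_rarefied_metric(table, region_depth(region), "PD",
                                       tree=tree,
                                       n_replicates=config.n_rarefactions,
                                       seed=config.seed)
            alpha_sr[region] = {r.sample_id: r.value for r in sr}
            alpha_pd[region] = {r.sample_id: r.value for r in pdv}
            alpha[region] = {
                "SR": alpha_sr[region],
                "PD": alpha_pd[region],
                "summary": {
                    "mean_SR": float(np.mean(list(alpha_sr[region].values()))),
                    "median_SR": float(np.median(list(alpha_sr[region].values()))),
                    "mean_PD": float(np.mean(list(alpha_pd[region].values()))),
                    "median_PD": float(np.median(list(alpha_pd[region].values()))),
                },
            }
        values, labels = [], []
        for region in regions:
            vals = list(alpha_sr[region].values())
            values += vals
            labels += [region] * len(vals)
        sr_anova = anova_tukey(values, labels)
        values, labels = [], []
        for region in regions:
            vals = list(alpha_pd[region].values())
            values += vals
            labels += [region] * len(vals)
        pd_anova = anova_tukey(values, labels)
        alpha["anova"] = {
            "SR": {"F": sr_anova.F, "p": sr_anova.p,
                   "letters": sr_anova.groupings},
            "PD": {"F": pd_anova.F, "p": pd_anova.p,
                   "letters": pd_anova.groupings},
        }
        if "alpha" in config.stages:
            report["alpha"] = alpha

    if "ma" in config.stages:
        ma: dict = {"SR": {}, "PD": {}, "SR_vs_PD": {}}
        for r1, r2 in combinations(regions, 2):
            common = [s for s in alpha_sr[r1] if s in alpha_sr[r2]]
            for metric, store in (("SR", alpha_sr), ("PD", alpha_pd)):
                fit = ma_fit([store[r1][s] for s in common],
                             [store[r2][s] for s in common])
                ma[metric][f"{r1}~{r2}"] = _fit_dict(fit)
        for region in regions:
            common = list(alpha_sr[region])
            fit = ma_fit([alpha_sr[region][s] for s in common],
                         [alpha_pd[region][s] for s in common])
            ma["SR_vs_PD"][region] = _fit_dict(fit)
        for metric in ("SR", "PD"):
            keys = list(ma[metric])
            fits = [ma[metric][k] for k in keys]
            letters = compare_slopes([
                type("F", (), {"slope_ci": (f["ci_low"], f["ci_high"])})()
                for f in fits])
            for k, letter in zip(keys, letters):
                ma[metric][k]["letter"] = letter
        report["ma"] = ma

    rarefied: dict[str, OTUTable] = {}
    rc_mats: dict[str, DissimilarityMatrix] = {}
    if "beta" in config.stages or "rank" in config.stages:
        for region in regions:
            rarefied[region] = rarefy(dataset.tables[region],
                                      region_depth(region),
                                      config.seed).drop_empty_otus()

    if "beta" in config.stages:
        # rarefaction subsampling is the dominant noise source for the
        # dissimilarity stage, so (as for SR/PD) matrices are averaged
        # over beta_rarefactions independent rarefaction replicates
        beta: dict = {"jaccard": {}, "bray_curtis": {}, "raup_crick": {},
                      "rc_comparison": {}}
        for region in regions:
            jac_vals, bc_vals, rc_vals = [], [], []
            sample_ids = None
            for rep in range(config.beta_rarefactions):
                rtab = rarefy(dataset.tables[region], region_depth(region),
                              config.seed + 7919 * rep).drop_empty_otus()
                if sample_ids is None:
                    sample_ids = rtab.sample_ids
                jac_vals.append(jaccard_matrix(rtab).values)
                bc_vals.append(bray_curtis_matrix(rtab).values)
                rc_vals.append(raup_crick(rtab, RCConfig(
                    n_iterations=config.rc_iterations,
                    weighting=config.rc_weighting,
                    seed=config.seed + 7919 * rep,
                    significance_band=config.significance_band,
                    share_sample_draws=True)).values)
            jac = DissimilarityMatrix(sample_ids,
                                      np.mean(jac_vals, axis=0), "jaccard")
            bc = DissimilarityMatrix(sample_ids,
                                     np.mean(bc_vals, axis=0), "bray_curtis")
            rc = DissimilarityMatrix(sample_ids,
                                     np.mean(rc_vals, axis=0), "raup_crick")
            rc_mats[region] = rc
            beta["jaccard"][region] = {
                "median": float(np.median(jac.condensed())),
                "mean": float(np.mean(jac.condensed()))}
            beta["bray_curtis"][region] = {
                "median": float(np.median(bc.condensed())),
                "mean": float(np.mean(bc.condensed()))}
            beta["raup_crick"][region] = {
                "mean": float(np.mean(rc.condensed())),
                "frac_significantly_similar": float(np.mean(
                    rc.condensed() <= -config.significance_band)),
                "frac_significantly_dissimilar": float(np.mean(
                    rc.condensed() >= config.significance_band))}
        for r1, r2 in combinations(regions, 2):
            comp = compare_rc_matrices(rc_mats[r1], rc_mats[r2],
                                       config.significance_band)
            beta["rc_comparison"][f"{r1}|{r2}"] = comp.counts
        report["beta"] = beta
        report["_rc_matrices"] = rc_mats   # in-memory only; not serialised

    if "rank" in config.stages:
        rank: dict = {"global_slope": {}, "ks_fraction_significant": {}}
        global_ra = {}
        for region in regions:
            ra = build_rank_abundance(rarefied[region], scope="global")
            global_ra[region] = ra
            rank["global_slope"][region] = loglog_slope(ra)
        per_lake = {region: build_rank_abundance(rarefied[region],
                                                 scope="per_lake")
                    for region in regions}
        for r1, r2 in combinations(regions, 2):
            _, p_global = ks_compare(global_ra[r1], global_ra[r2])
            lakes = [s for s in per_lake[r1] if s in per_lake[r2]]
            pvals = [ks_compare(per_lake[r1][s], per_lake[r2][s])[1]
                     for s in lakes]
            rank["ks_fraction_significant"][f"{r1}|{r2}"] = float(
                np.mean([p < config.ks_alpha for p in pvals]))
            rank.setdefault("ks_global_p", {})[f"{r1}|{r2}"] = float(p_global)
        report["rank"] = rank

    if "arisa" in config.stages and dataset.arisa_profiles:
        fp = bin_peaks(dataset.arisa_profiles)
        richness = arisa_richness(fp)
        arisa: dict = {"frame_offset": fp.frame_offset,
                       "richness": {k: int(v) for k, v in richness.items()},
                       "regressions": {}}
        for region in regions:
            lakes = [s for s in dataset.tables[region].sample_ids
                     if s in richness and s in alpha_sr.get(region, {})]
            if len(lakes) >= 3:
                fit = linear_regression(
                    [richness[s] for s in lakes],
                    [alpha_sr[region][s] for s in lakes])
                arisa["regressions"][region] = {
                    "slope": fit.slope, "F": fit.F, "p": fit.p,
                    "r2": fit.r2, "n": fit.n}
        report["arisa"] = arisa

    if "classes" in config.stages and dataset.species_classes:
        tabs = {region: class_abundance_table(dataset.tables[region],
                                              dataset.species_classes)
                for region in regions}
        top = top_classes(tabs, k=config.n_top_classes)
        tabs = {region: t[top] for region, t in tabs.items()}
        cls: dict = {"top_classes": top, "paired_t": {}}
        for r1, r2 in combinations(regions, 2):
            res = paired_class_tests(tabs[r1], tabs[r2])
            cls["paired_t"][f"{r1}|{r2}"] = {
                c: {"t": float(res.loc[c, "t"]), "p": float(res.loc[c, "p"])}
                for c in res.index}
        report["classes"] = cls
    return report


def centroid_tree(centroid_reads) -> TreeNode:
    """UPGMA tree over clustering centroids from Hamming distances.

    Stands in for a phylogeny when OTUs come from de novo clustering of
    synthetic reads; adequate for monotonicity/direction analyses, not
    for phylogenetic inference.
    """
    seqs = [r.sequence for r in centroid_reads]
    ids = [r.id for r in centroid_reads]
    if len(seqs) < 2:
        raise ValueError("need >= 2 centroids for a tree")
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1)
    dist = pdist(mat, metric="hamming")
    linkage = average(dist)
    tree = TreeNode.from_linkage_matrix(linkage, ids)
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length < 0:
            node.length = 0.0
    return tree


def sst_sweep(region_reads: dict[str, dict], config: PipelineConfig,
              depth: int | None = None,
              n_rarefactions: int = 100,
              compute_pd: bool = True) -> dict:
    """Cluster -> rarefy -> SR/PD -> beta -> rank-abundance slope per SST.

    ``region_reads`` maps region name to per-sample trimmed ReadSets.
    Returns ``{region: {sst: {...}}}`` with OTU counts, mean rarefied
    SR (and PD over a centroid tree), mean Jaccard / Bray-Curtis
    dissimilarity and the global log-log rank-abundance slope.

    The sweep is nested: reads are clustered once at the strictest
    threshold and centroids are then merged at each looser threshold,
    so partitions refine one another and OTU counts and richness are
    non-increasing along the sweep by construction.
    """
    out: dict = {}
    for region, sample_reads in region_reads.items():
        totals = [len(rs) for rs in sample_reads.values()]
        use_depth = depth or min(totals)
        out[region] = {}
        result = None
        for sst in sorted(config.sst_grid, reverse=True):
            result = greedy_cluster(sample_reads, sst) if result is None \
                else merge_centroids(result, sst)
            table = result.otu_table
            sr = mean_rarefied_metric(table, use_depth, "SR",
                                      n_replicates=n_rarefactions,
                                      seed=config.seed)
            entry = {
                "n_otus": result.n_otus,
                "mean_SR": float(np.mean([r.value for r in sr])),
            }
            if compute_pd and result.n_otus >= 2:
                tree = centroid_tree(result.centroids)
                pdv = mean_rarefied_metric(table, use_depth, "PD", tree=tree,
                                           n_replicates=n_rarefactions,
                                           seed=config.seed)
                entry["mean_PD"] = float(np.mean([r.value for r in pdv]))
            rtab = rarefy(table, use_depth, config.seed).drop_empty_otus()
            entry["mean_jaccard"] = float(np.mean(
                jaccard_matrix(rtab).condensed()))
            entry["mean_bray_curtis"] = float(np.mean(
                bray_curtis_matrix(rtab).condensed()))
            ra = build_rank_abundance(rtab, scope="global")
            if ra.abundances.size >= 2:
                entry["global_loglog_slope"] = loglog_slope(ra)
            out[region][f"{sst:.2f}"] = entry
    return out


def write_report(report: dict, outdir) -> Path:
    """Serialise the report deterministically (sorted-key JSON + TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rc_mats = report.pop("_rc_matrices", None)
    if rc_mats:
        for region, mat in rc_mats.items():
            mat.to_dataframe().to_csv(outdir / f"rc_{region}.tsv", sep="\t")
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return path


def demo(outdir, seed: int = 0) -> dict:
    """Seeded synthetic 20-lake demonstration of the full comparison.

    Uses the default metacommunity (300 species, 20 lakes, 1500 reads
    per lake, V4 resolved finer than V3/V5) with the repeat counts
    scaled for an interactive run: 250 rarefaction replicates for SR/PD
    and 400 Raup-Crick iterations per beta rarefaction replicate.
    """
    config = PipelineConfig(
        truth=TruthConfig(seed=seed),
        n_rarefactions=250,
        rc_iterations=400,
        seed=seed,
    )
    report = run_pipeline(config)
    write_report(report, outdir)
    return report
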