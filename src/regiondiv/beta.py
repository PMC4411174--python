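"""Beta diversity: Jaccard, Bray-Curtis and the Raup-Crick null model.

The modified Raup-Crick index compares the observed number of shared
species in a sample pair with a null distribution obtained by
re-assembling both samples at their observed richness from the
dataset-wide species pool (gamma diversity).  With tail probability
``p = [#(SS_null > SS_obs) + 1/2 #(SS_null = SS_obs)] / N`` the index is
``RC = 2p - 1``: values near +1 mean the samples share *fewer* species
than chance (significantly more dissimilar), values near -1 mean they
share more (significantly more similar), with +-0.975 as the
conventional significance band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom

from ._seeds import rng_for
from .types import OTUTable

__all__ = [
    "DissimilarityMatrix",
    "RCConfig",
    "jaccard",
    "bray_curtis",
    "jaccard_matrix",
    "bray_curtis_matrix",
    "raup_crick",
    "rc_exhaustive",
    "classify_rc_pair",
    "compare_rc_matrices",
    "RCComparison",
]


@dataclass
class DissimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Presence-absence Jaccard dissimilarity; two empty samples -> 0."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("count vectors differ in length")
    pa, pb = a > 0, b > 0
    union = int((pa | pb).sum())
    if union == 0:
        return 0.0
    return 1.0 - int((pa & pb).sum()) / union


def bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    """Abundance-based Bray-Curtis: sum|a-b| / sum(a+b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("count vectors differ in length")
    denom = float((a + b).sum())
    if denom == 0:
        raise ValueError("both samples are empty")
    return float(np.abs(a - b).sum() / denom)


def jaccard_matrix(table: OTUTable) -> DissimilarityMatrix:
    P = table.presence().astype(np.int64)
    inter = P @ P.T
    sizes = P.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(vals, 0.0)
    return DissimilarityMatrix(list(table.sample_ids), vals, "jaccard")


def bray_curtis_matrix(table: OTUTable) -> DissimilarityMatrix:
    if (table.sample_sums() == 0).any():
        raise ValueError("empty sample in table")
    vals = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DissimilarityMatrix(list(table.sample_ids), vals, "bray_curtis")


@dataclass
class RCConfig:
    n_iterations: int = 10000
    weighting: str = "occurrence_frequency"   # or "uniform"
    seed: int = 0
    significance_band: float = 0.975
    # draw each sample's null communities once and reuse them across its
    # pairs (same per-pair marginal law, ~20x faster for many samples);
    # False draws fresh nulls per pair from a pair-keyed seed
    share_sample_draws: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.weighting not in ("occurrence_frequency", "uniform"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if not 0.0 < self.significance_band < 1.0:
            raise ValueError("significance band must lie in (0, 1)")


def _null_draws(rng: np.random.Generator, weights: np.ndarray,
                alpha: int, n_iter: int) -> np.ndarray:
    """Boolean (n_iter x gamma) membership of weighted draws w/o replacement.

    Uses the Gumbel top-k construction, equivalent to drawing ``alpha``
    species sequentially without replacement with probability
    proportional to ``weights``.
    """
    gamma = weights.size
    keys = np.log(weights)[None, :] + rng.gumbel(size=(n_iter, gamma))
    idx = np.argpartition(-keys, alpha - 1, axis=1)[:, :alpha]
    member = np.zeros((n_iter, gamma), dtype=bool)
    member[np.arange(n_iter)[:, None], idx] = True
    return member


def raup_crick(table: OTUTable, config: RCConfig) -> DissimilarityMatrix:
    """Monte-Carlo Raup-Crick dissimilarity for every sample pair.

    The species pool is the set of OTUs present anywhere in the table
    (per dataset, never across datasets); null richness equals each
    sample's observed richness.  Pair-level RNGs derive from the config
    seed and the pair indices, so the matrix is exactly symmetric.
    """
    P = table.presence()
    pool = P.any(axis=0)
    P = P[:, pool]
    gamma = int(P.shape[1])
    alphas = P.sum(axis=1)
    if (alphas == 0).any():
        empty = [s for s, a in zip(table.sample_ids, alphas) if a == 0]
        raise ValueError(f"empty sample(s): {empty}")
    if config.weighting == "occurrence_frequency":
        weights = P.sum(axis=0).astype(float)
    else:
        weights = np.ones(gamma)
    n = table.n_samples
    vals = np.zeros((n, n))
    if config.share_sample_draws:
        draws = [
            _null_draws(rng_for(config.seed, "rc-sample", i), weights,
                        int(alphas[i]), config.n_iterations)
            for i in range(n)
        ]
        for i in range(n):
            for j in range(i + 1, n):
                ss_obs = int((P[i] & P[j]).sum())
                ss_null = (draws[i] & draws[j]).sum(axis=1)
                p = ((ss_null > ss_obs).sum()
                     + 0.5 * (ss_null == ss_obs).sum()) / config.n_iterations
                vals[i, j] = vals[j, i] = 2.0 * p - 1.0
        return DissimilarityMatrix(list(table.sample_ids), vals, "raup_crick")
    for i in range(n):
        for j in range(i + 1, n):
            rng = rng_for(config.seed, "raup-crick", i, j)
            ss_obs = int((P[i] & P[j]).sum())
            mi = _null_draws(rng, weights, int(alphas[i]),
                             config.n_iterations)
            mj = _null_draws(rng, weights, int(alphas[j]),
                             config.n_iterations)
            ss_null = (mi & mj).sum(axis=1)
            p = ((ss_null > ss_obs).sum()
                 + 0.5 * (ss_null == ss_obs).sum()) / config.n_iterations
            vals[i, j] = vals[j, i] = 2.0 * p - 1.0
    return DissimilarityMatrix(list(table.sample_ids), vals, "raup_crick")


def rc_exhaustive(table: OTUTable, config: RCConfig | None = None,
                  max_gamma: int = 12) -> DissimilarityMatrix:
    """Exact Raup-Crick for tiny uniform-weighting pools.

    Under uniform weighting the null shared-species count for richness
    pair ``(a, b)`` from a pool of ``gamma`` follows a hypergeometric
    law ``SS ~ Hypergeom(gamma, a, b)``; the exact tail probability
    (same half-weight tie rule as :func:`raup_crick`) replaces the
    Monte-Carlo estimate.
    """
    if config is not None and config.weighting != "uniform":
        raise ValueError("exhaustive mode requires uniform weighting")
    P = table.presence()
    pool = P.any(axis=0)
    P = P[:, pool]
    gamma = int(P.shape[1])
    if gamma > max_gamma:
        raise ValueError(f"pool of {gamma} species too large to enumerate")
    alphas = P.sum(axis=1)
    if (alphas == 0).any():
        raise ValueError("empty sample")
    n = table.n_samples
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = int(alphas[i]), int(alphas[j])
            ss_obs = int((P[i] & P[j]).sum())
            dist = hypergeom(gamma, a, b)
            p = float(dist.sf(ss_obs) + 0.5 * dist.pmf(ss_obs))
            vals[i, j] = vals[j, i] = 2.0 * p - 1.0
    return DissimilarityMatrix(list(table.sample_ids), vals, "raup_crick")


def _verdict(rc: float, band: float) -> str:
    if rc <= -band:
        return "similar"
    if rc >= band:
        return "dissimilar"
    return "neutral"


def classify_rc_pair(rc1: float, rc2: float, band: float = 0.975) -> str:
    """Agreement category of one lake pair judged by two regions.

    ``a``: same verdict; ``b``: one significantly similar, one neutral;
    ``c``: one significantly dissimilar, one neutral; ``d``: opposite
    significant verdicts.
    """
    if not 0.0 < band < 1.0:
        raise ValueError("band must lie in (0, 1)")
    for rc in (rc1, rc2):
        if not -1.0 <= rc <= 1.0:
            raise ValueError("RC values must lie in [-1, 1]")
    v1, v2 = _verdict(rc1, band), _verdict(rc2, band)
    if v1 == v2:
        return "a"
    verdicts = {v1, v2}
    if verdicts == {"similar", "neutral"}:
        return "b"
    if verdicts == {"dissimilar", "neutral"}:
        return "c"
    return "d"


@dataclass
class RCComparison:
    pair_categories: dict[tuple[str, str], str]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {c: 0 for c in "abcd"}
            for cat in self.pair_categories.values():
                self.counts[cat] += 1


def compare_rc_matrices(rc1: DissimilarityMatrix, rc2: DissimilarityMatrix,
                        band: float = 0.975) -> RCComparison:
    """Classify every sample pair by the two regions' RC verdicts."""
    if rc1.sample_ids != rc2.sample_ids:
        raise ValueError("RC matrices cover different samples")
    cats = {}
    ids = rc1.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            cats[(ids[i], ids[j])] = classify_rc_pair(
                rc1.values[i, j], rc2.values[i, j], band)
    return RCComparison(pair_categories=cats)
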