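"""Alpha diversity: rarefaction, species richness and Faith's PD.

Rarefaction is a uniform subsample *without replacement* (multivariate
hypergeometric) to a fixed depth.  Because a single rarefaction is
noisy, the headline estimator repeats it (default 1000 times) and
averages the metric.  Faith's phylogenetic diversity is the summed
branch length of the minimal rooted subtree spanning the observed OTUs;
the root's own edge, if present in the Newick source, is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from skbio import TreeNode

from ._seeds import rng_for
from .types import OTUTable

__all__ = [
    "AlphaResult",
    "rarefy",
    "species_richness",
    "faith_pd",
    "mean_rarefied_metric",
    "expected_rarefied_richness",
    "TreeIncidence",
]


@dataclass
class AlphaResult:
    sample_id: str
    metric: str                 # "SR" or "PD"
    value: float
    n_replicates: int
    rarefaction_depth: int


def rarefy(table: OTUTable, depth: int, seed: int) -> OTUTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning;
    if no sample reaches the depth an error is raised.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = rng_for(seed, "rarefy")
    totals = table.sample_sums()
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} sample(s) below depth "
                      f"{depth}: {dropped}", stacklevel=2)
    rows = []
    for i in np.nonzero(keep)[0]:
        rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
    return OTUTable(
        sample_ids=[s for s, k in zip(table.sample_ids, keep) if k],
        otu_ids=list(table.otu_ids),
        counts=np.vstack(rows),
        region_label=table.region_label,
    )


def species_richness(row: np.ndarray) -> int:
    """Number of OTUs with count > 0."""
    row = np.asarray(row)
    if (row < 0).any():
        raise ValueError("negative counts")
    return int((row > 0).sum())


class TreeIncidence:
    """Edge-by-tip incidence of a rooted tree, for fast repeated PD.

    Edge ``e`` (every non-root node) subtends a set of tips; PD of a
    presence vector is the sum of lengths of edges subtending at least
    one present tip.
    """

    def __init__(self, tree: TreeNode):
        tips = [t.name for t in tree.tips()]
        if len(tips) != len(set(tips)):
            raise ValueError("duplicate tip labels")
        self.tip_ids = tips
        self.tip_index = {t: i for i, t in enumerate(tips)}
        edges = [n for n in tree.postorder(include_self=False)]
        lengths = []
        for n in edges:
            if n.length is None:
                raise ValueError("missing branch length")
            lengths.append(float(n.length))
        self.lengths = np.asarray(lengths)
        inc = np.zeros((len(edges), len(tips)), dtype=bool)
        # postorder guarantees children are visited before parents
        below: dict[int, np.ndarray] = {}
        for ei, n in enumerate(edges):
            if n.is_tip():
                mask = np.zeros(len(tips), dtype=bool)
                mask[self.tip_index[n.name]] = True
            else:
                mask = np.zeros(len(tips), dtype=bool)
                for child in n.children:
                    mask |= below[id(child)]
            below[id(n)] = mask
            inc[ei] = mask
        self.incidence = inc

    def presence_vector(self, present: set[str]) -> np.ndarray:
        missing = present - set(self.tip_ids)
        if missing:
            raise ValueError(
                f"OTU(s) not found as tree tips: {sorted(missing)}")
        vec = np.zeros(len(self.tip_ids), dtype=bool)
        for t in present:
            vec[self.tip_index[t]] = True
        return vec

    def pd(self, presence: np.ndarray) -> float:
        """PD of one boolean tip-presence vector (canonical summation)."""
        used = self.incidence[:, presence].any(axis=1)
        return float(np.sort(self.lengths[used]).sum())

    def pd_many(self, presence_matrix: np.ndarray) -> np.ndarray:
        """PD of many presence vectors at once (rows = replicates)."""
        edge_hit = presence_matrix.astype(np.float64) @ self.incidence.T.astype(
            np.float64) > 0
        return edge_hit @ self.lengths


def faith_pd(row: np.ndarray, otu_ids: list[str], tree: TreeNode) -> float:
    """Faith's PD of one sample: summed lengths of the rooted spanning subtree.

    Every OTU with count > 0 must be a tip of ``tree``; extra tips in the
    tree are allowed.
    """
    row = np.asarray(row)
    present = {o for o, c in zip(otu_ids, row) if c > 0}
    if not present:
        return 0.0
    inc = TreeIncidence(tree)
    return inc.pd(inc.presence_vector(present))


def expected_rarefied_richness(row: np.ndarray, depth: int) -> float:
    """Closed-form E[SR] under without-replacement rarefaction.

    ``E[SR] = sum_i (1 - C(T - t_i, d) / C(T, d))`` with total ``T`` and
    per-OTU counts ``t_i``; evaluated with log-gamma for stability.
    """
    row = np.asarray(row, dtype=np.int64)
    total = int(row.sum())
    if depth > total:
        raise ValueError("depth exceeds sample total")
    t = row[row > 0].astype(np.float64)
    with np.errstate(invalid="ignore"):
        logp_miss = (gammaln(total - t + 1) - gammaln(total - t - depth + 1)
                     - gammaln(total + 1) + gammaln(total - depth + 1))
    p_miss = np.where(total - t < depth, 0.0, np.exp(logp_miss))
    return float(np.sum(1.0 - p_miss))


def mean_rarefied_metric(table: OTUTable, depth: int, metric: str,
                         tree: TreeNode | None = None,
                         n_replicates: int = 1000,
                         seed: int = 0) -> list[AlphaResult]:
    """Average SR or PD over repeated independent rarefactions.

    Samples below ``depth`` are dropped (with a warning) as in
    :func:`rarefy`.  Replicate draws derive deterministically from
    ``seed``; one fixed tree is shared across replicates for PD.
    """
    if metric not in ("SR", "PD"):
        raise ValueError("metric must be 'SR' or 'PD'")
    if metric == "PD" and tree is None:
        raise ValueError("PD requires a tree")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    totals = table.sample_sums()
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} sample(s) below depth "
                      f"{depth}: {dropped}", stacklevel=2)
    inc = None
    col_idx = None
    if metric == "PD":
        inc = TreeIncidence(tree)
        nonzero = table.counts.sum(axis=0) > 0
        really_missing = [o for o, nz in zip(table.otu_ids, nonzero)
                          if nz and o not in inc.tip_index]
        if really_missing:
            raise ValueError(
                f"OTU(s) not found as tree tips: {really_missing[:5]}")
        col_idx = np.array([inc.tip_index.get(o, -1) for o in table.otu_ids])
    results = []
    for i in np.nonzero(keep)[0]:
        rng = rng_for(seed, "mean-rarefied", metric, int(i))
        draws = rng.multivariate_hypergeometric(
            table.counts[i], depth, size=n_replicates)
        if metric == "SR":
            value = float((draws > 0).sum(axis=1).mean())
        else:
            presence = np.zeros((n_replicates, len(inc.tip_ids)), dtype=bool)
            pos = col_idx >= 0
            presence[:, col_idx[pos]] = draws[:, pos] > 0
            value = float(inc.pd_many(presence).mean())
        results.append(AlphaResult(
            sample_id=table.sample_ids[int(i)], metric=metric, value=value,
            n_replicates=n_replicates, rarefaction_depth=depth))
    return results
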