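"""Rank-abundance distributions, KS comparison, log-log slope fitting.

A rank-abundance distribution sorts OTU abundances descending against
rank.  Shapes are compared with a two-sample Kolmogorov-Smirnov test in
which each OTU contributes its abundance as one observation, making the
test well defined and sample-size aware.  For the clustering-threshold
sweep, the distribution is summarised by the OLS slope of
log(abundance) on log(rank).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import OTUTable

__all__ = ["RankAbundance", "build_rank_abundance", "ks_compare",
           "loglog_slope"]


@dataclass
class RankAbundance:
    scope: str                 # "per_lake" or "global"
    abundances: np.ndarray     # sorted non-increasing, all > 0
    sample_id: str | None = None
    rank_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.size == 0:
            raise ValueError("empty rank-abundance distribution")
        if (self.abundances <= 0).any():
            raise ValueError("abundances must be positive")
        if (np.diff(self.abundances) > 0).any():
            raise ValueError("abundances must be sorted non-increasing")

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, self.abundances.size + 1)

    def windowed(self, lo: int, hi: int) -> "RankAbundance":
        """Restrict to ranks lo..hi (1-based, inclusive)."""
        if not 1 <= lo <= hi:
            raise ValueError("invalid rank window")
        sub = self.abundances[lo - 1:hi]
        return RankAbundance(scope=self.scope, abundances=sub,
                             sample_id=self.sample_id, rank_window=(lo, hi))


def build_rank_abundance(table: OTUTable, scope: str = "global"):
    """Per-lake or pooled rank-abundance distributions.

    ``scope="global"`` sums counts over all samples and returns a single
    distribution; ``scope="per_lake"`` returns a dict keyed by sample.
    Zero-count OTUs are excluded.
    """
    if scope not in ("global", "per_lake"):
        raise ValueError(f"unknown scope {scope!r}")
    if table.counts.sum() == 0:
        raise ValueError("empty OTU table")
    if scope == "global":
        totals = table.counts.sum(axis=0)
        vals = np.sort(totals[totals > 0])[::-1]
        return RankAbundance(scope="global", abundances=vals)
    out = {}
    for i, sample in enumerate(table.sample_ids):
        row = table.counts[i]
        vals = np.sort(row[row > 0])[::-1]
        if vals.size:
            out[sample] = RankAbundance(scope="per_lake", abundances=vals,
                                        sample_id=sample)
    return out


def ks_compare(ra1: RankAbundance, ra2: RankAbundance):
    """Two-sample KS test on the two abundance-value distributions.

    Returns ``(D, p)`` with the asymptotic two-sided p-value.
    """
    if ra1.abundances.size == 0 or ra2.abundances.size == 0:
        raise ValueError("empty rank-abundance input")
    res = stats.ks_2samp(ra1.abundances, ra2.abundances, method="asymp")
    return float(res.statistic), float(res.pvalue)


def loglog_slope(ra: RankAbundance) -> float:
    """OLS slope of log(abundance) on log(rank); needs >= 2 ranks."""
    if ra.abundances.size < 2:
        raise ValueError("log-log slope needs at least 2 ranks")
    x = np.log(ra.ranks.astype(float))
    y = np.log(ra.abundances)
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
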