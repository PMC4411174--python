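"""Cross-region comparison statistics.

One-way ANOVA with Tukey HSD letters for SR/PD across regions, paired
t-tests on taxonomic class abundances, and simple OLS with the overall
F test for ARISA-vs-sequencing and environmental relationships.  Letter
grouping uses the same transitive-closure rule as the model-II module:
levels whose pairwise Tukey comparisons are non-significant share a
letter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["GroupComparison", "anova_tukey", "paired_class_tests",
           "linear_regression", "LinearFit", "top_classes"]


@dataclass
class GroupComparison:
    factor: str
    F: float
    p: float
    groupings: dict[str, str]   # level -> letter


def _closure_letters(levels: list[str], nonsig_pairs: set[frozenset]) -> dict[str, str]:
    parent = {lv: lv for lv in levels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair in nonsig_pairs:
        a, b = tuple(pair)
        parent[find(a)] = find(b)
    roots: dict[str, str] = {}
    out = {}
    for lv in levels:
        r = find(lv)
        if r not in roots:
            roots[r] = chr(ord("a") + len(roots))
        out[lv] = roots[r]
    return out


def anova_tukey(values, groups, factor: str = "region",
                alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA plus Tukey-HSD letter groupings at ``alpha``."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == lv] for lv in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    F, p = sps.f_oneway(*samples)
    tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    nonsig = set()
    for row in tk.summary().data[1:]:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
        if not reject:
            nonsig.add(frozenset((g1, g2)))
    letters = _closure_letters([str(lv) for lv in levels], nonsig)
    return GroupComparison(factor=factor, F=float(F), p=float(p),
                           groupings=letters)


def paired_class_tests(t1: pd.DataFrame, t2: pd.DataFrame) -> pd.DataFrame:
    """Per-class paired t-tests between two class-abundance tables.

    Tables are samples x classes relative abundances with identical
    indices and columns; pairs are matched by sample id.  Degenerate
    zero-variance differences report ``t = +-inf`` with p = 0 (or
    ``t = 0, p = 1`` when the difference is identically zero).
    """
    if set(t1.index) != set(t2.index):
        raise ValueError("tables cover different samples")
    if list(t1.columns) != list(t2.columns):
        raise ValueError("tables cover different classes")
    t2 = t2.loc[t1.index]
    rows = []
    for cls in t1.columns:
        d = t1[cls].to_numpy(float) - t2[cls].to_numpy(float)
        sd = d.std(ddof=1)
        scale = max(np.abs(d).max(), 1e-300)
        if sd <= 1e-12 * scale:
            if np.allclose(d, 0):
                t_stat, p = 0.0, 1.0
            else:
                t_stat = np.inf if d.mean() > 0 else -np.inf
                p = 0.0
        else:
            t_stat, p = sps.ttest_rel(t1[cls], t2[cls])
        rows.append((cls, float(t_stat), float(p)))
    return pd.DataFrame(rows, columns=["class", "t", "p"]).set_index("class")


@dataclass
class LinearFit:
    slope: float
    intercept: float
    F: float
    p: float
    r2: float
    n: int


def linear_regression(x, y) -> LinearFit:
    """Ordinary least squares with the overall F test (= slope t-test)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0:
        raise ValueError("constant x")
    res = sps.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     F=float(t * t), p=float(res.pvalue),
                     r2=float(res.rvalue ** 2), n=int(x.size))


def top_classes(tables: dict[str, pd.DataFrame], k: int = 10) -> list[str]:
    """The k most abundant classes, ranked by mean relative abundance
    jointly across all samples of all regions."""
    pooled = pd.concat(tables.values(), axis=0)
    means = pooled.mean(axis=0).sort_values(ascending=False)
    return list(means.index[:k])
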