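"""Major-axis (model II) regression with confidence intervals.

Model II regression is appropriate when both variables carry sampling
error, as when comparing richness estimates of the same lakes from two
sequencing targets.  The MA slope is the direction of the first
principal axis of the sample covariance:

    b = (s_yy - s_xx + sqrt((s_yy - s_xx)^2 + 4 s_xy^2)) / (2 s_xy)

and the 95% CI rotates the axis by the critical angle of Jolicoeur's
F-based statistic (the tangent-addition form used by standard model-II
regression software).  Two slopes are deemed indistinguishable when
their CIs overlap; overlap groups are closed transitively into letters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MAFit", "ma_fit", "compare_slopes"]


@dataclass
class MAFit:
    slope: float
    intercept: float
    r2: float
    slope_ci: tuple[float, float]
    n: int

    def differs_from(self, value: float) -> bool:
        """True when ``value`` lies outside the 2.5-97.5% slope interval."""
        lo, hi = self.slope_ci
        return not (lo <= value <= hi)


def ma_fit(x, y, alpha: float = 0.05) -> MAFit:
    """Major-axis regression of y on x with a (1 - alpha) slope CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("MA regression needs n >= 3")
    s_xx = np.var(x, ddof=1)
    s_yy = np.var(y, ddof=1)
    s_xy = np.cov(x, y, ddof=1)[0, 1]
    if s_xx == 0 or s_yy == 0:
        raise ValueError("constant x or y")
    if s_xy == 0:
        raise ValueError("zero covariance: MA slope undefined "
                         "(the major axis is parallel to an axis)")
    d = s_yy - s_xx
    slope = (d + np.sqrt(d * d + 4 * s_xy * s_xy)) / (2 * s_xy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r * r)

    # Jolicoeur's CI: rotate the major axis by atan(A) in both directions
    lam = np.linalg.eigvalsh(np.array([[s_xx, s_xy], [s_xy, s_yy]]))
    lam2, lam1 = float(lam[0]), float(lam[1])
    if lam2 <= 0:  # perfectly collinear data: zero-width interval
        ci = (float(slope), float(slope))
    else:
        # critical rotation of the principal axis: Var(angle) is
        # asymptotically lam1*lam2 / ((lam1-lam2)^2 * n)  (Anderson)
        H = stats.f.ppf(1 - alpha, 1, n - 2) / (
            (lam1 / lam2 + lam2 / lam1 - 2.0) * (n - 2))
        if H >= 1:
            ci = (-np.inf, np.inf)  # slope unconstrained at this alpha
        else:
            A = np.sqrt(H / (1.0 - H))
            denom_lo = 1.0 + slope * A
            denom_hi = 1.0 - slope * A
            lo = (slope - A) / denom_lo if denom_lo > 0 else -np.inf
            hi = (slope + A) / denom_hi if denom_hi > 0 else np.inf
            ci = (float(lo), float(hi))
    return MAFit(slope=float(slope), intercept=intercept, r2=r2,
                 slope_ci=ci, n=int(n))


def compare_slopes(fits: list[MAFit]) -> list[str]:
    """Group fits whose slope CIs overlap; transitive closure applied.

    Returns one letter per fit; fits sharing a letter cannot be
    distinguished at the CI level.  Chained overlaps (a-b and b-c but
    not a-c) collapse into a single group by design.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n = len(fits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            lo_i, hi_i = fits[i].slope_ci
            lo_j, hi_j = fits[j].slope_ci
            if lo_i <= hi_j and lo_j <= hi_i:
                parent[find(i)] = find(j)
    roots: dict[int, str] = {}
    letters = []
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = chr(ord("a") + len(roots))
        letters.append(roots[r])
    return letters
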