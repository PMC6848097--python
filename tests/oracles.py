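"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately written from a different route than the
implementation it checks: explicit loops and textbook formulas instead
of vectorized linear algebra, scipy's multivariate-normal integrator
instead of the Owen's-T identity, and a generic scalar optimizer
instead of margin-matched root finding.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar


def isd_brute(values) -> float:
    """Sample SD via the explicit sum-of-squares formula."""
    v = list(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    return math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1))


def rank_brute(a) -> list[float]:
    """Average ranks by explicit tie-group bookkeeping."""
    a = list(a)
    order = sorted(range(len(a)), key=lambda i: a[i])
    ranks = [0.0] * len(a)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and a[order[j + 1]] == a[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def partial_spearman_brute(x, y, C):
    """Compose independent rank, OLS-residual and correlation steps."""
    import statsmodels.api as sm

    rx = np.array(rank_brute(x))
    ry = np.array(rank_brute(y))
    RC = np.column_stack([rank_brute(C[:, j]) for j in range(C.shape[1])])
    ex = sm.OLS(rx, sm.add_constant(RC)).fit().resid
    ey = sm.OLS(ry, sm.add_constant(RC)).fit().resid
    rho = np.corrcoef(ex, ey)[0, 1]
    n, k = len(x), C.shape[1]
    df = n - 2 - k
    t = rho * math.sqrt(df / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), df)
    return rho, p


def bh_brute(pvals) -> list[float]:
    """Benjamini-Hochberg step-up applied by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = pvals[i] * m / rank_from_top
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj


def kruskal_brute(values, groups):
    """Kruskal-Wallis H from the rank-sum formula with tie correction."""
    values = list(values)
    n = len(values)
    ranks = rank_brute(values)
    labels = sorted(set(groups), key=list(groups).index)
    H = 0.0
    for g in labels:
        idx = [i for i, gg in enumerate(groups) if gg == g]
        Rg = sum(ranks[i] for i in idx)
        H += Rg**2 / len(idx)
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    # tie correction
    from collections import Counter

    ties = Counter(values)
    T = sum(t**3 - t for t in ties.values())
    corr = 1.0 - T / (n**3 - n)
    if corr > 0:
        H /= corr
    p = stats.chi2.sf(H, len(labels) - 1)
    return H, p


def tetrachoric_brute(cells) -> float:
    """ML tetrachoric by scalar optimization of the multinomial likelihood.

    Cell probabilities are integrated with scipy's multivariate-normal
    CDF; thresholds are profiled out at the sample margins.
    """
    cells = np.asarray(cells, dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    n = cells.sum()
    p1x = cells[1].sum() / n
    p1y = cells[:, 1].sum() / n
    tx = stats.norm.ppf(1 - p1x)
    ty = stats.norm.ppf(1 - p1y)

    def nll(rho):
        mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        p00 = mvn.cdf([tx, ty])
        p0x = stats.norm.cdf(tx)   # P(x = 0)
        p0y = stats.norm.cdf(ty)   # P(y = 0)
        # cell order (n00, n01, n10, n11):
        probs = np.array(
            [p00, p0x - p00, p0y - p00, 1 - p0x - p0y + p00]
        )
        probs = np.clip(probs, 1e-12, None)
        counts = np.array([cells[0, 0], cells[0, 1], cells[1, 0], cells[1, 1]])
        return -float(counts @ np.log(probs))

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-7})
    return float(res.x)
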