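"""Covariate-adjusted rank correlations and extreme-group contrasts.

The core statistic is the partial Spearman correlation: rank-transform
the two variables and each covariate (average ranks), residualize both
ranked variables on the ranked covariates plus an intercept by least
squares, and correlate the residuals.  Inference uses the t
approximation with ``n - 2 - k`` degrees of freedom (k covariates).

The full association grid crosses the personality scores (HPS total
plus three subscale scores) with the 21-variable sleep panel (14
actigraphy means/ISDs + 7 PSQI-derived variables), with per-pair
complete-case samples, joint multiple-testing correction
(Benjamini-Hochberg by default), Steiger's Z for comparing dependent
correlations, and nearest-rank decile extreme groups contrasted by
tie-corrected Kruskal-Wallis tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ConstantInputError, DataError

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("hps_total", "score_core", "score_vitality", "score_ordinariness")

_ADJUST_METHODS = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}


@dataclass(frozen=True)
class PartialCorrResult:
    rho: float
    p: float
    n: int


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average", axis=0)


def _residualize(y: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of y on [1, C] by least squares."""
    n = y.shape[0]
    X = np.ones((n, 1)) if C is None or C.size == 0 else np.column_stack([np.ones(n), C])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_spearman(x, y, covariates=None) -> PartialCorrResult:
    """Partial Spearman correlation of x and y given covariates.

    Constant covariates are dropped (logged); a constant x or y is an
    error because its ranks carry no information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    if not (len(x) == len(y) == len(C)):
        raise DataError("x, y, covariates must be row-aligned")
    keep = [j for j in range(C.shape[1]) if len(np.unique(C[:, j])) > 1]
    if len(keep) < C.shape[1]:
        logger.info("dropping %d constant covariates", C.shape[1] - len(keep))
    C = C[:, keep]
    k = C.shape[1]
    n = len(x)
    if n < k + 4:
        raise DataError(f"need at least k + 4 = {k + 4} observations, got {n}")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ConstantInputError("partial Spearman undefined for constant x or y")

    rx = _residualize(_rank(x)[:, None], _rank(C) if k else None)[:, 0]
    ry = _residualize(_rank(y)[:, None], _rank(C) if k else None)[:, 0]
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ConstantInputError("residual variance is zero")
    rho = float(rx @ ry) / denom
    rho = max(-1.0, min(1.0, rho))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return PartialCorrResult(rho=rho, p=min(p, 1.0), n=n)


def correlate_grid(
    scores: pd.DataFrame,
    sleep: pd.DataFrame,
    covariates: pd.DataFrame,
    score_cols=None,
    sleep_cols=None,
) -> pd.DataFrame:
    """One association record per (personality score, sleep variable) pair.

    Tables join on ``subject_id``; each pair is computed on its own
    complete cases, so actigraphy and PSQI subsamples may differ in n.
    Records are ordered score-major in the given panel order.
    """
    score_cols = list(score_cols or [c for c in SCORE_COLUMNS if c in scores.columns])
    sleep_cols = list(sleep_cols or [c for c in sleep.columns if c != "subject_id"])
    for c in score_cols:
        if c not in scores.columns:
            raise ConfigurationError(f"score column {c!r} missing")
    for c in sleep_cols:
        if c not in sleep.columns:
            raise ConfigurationError(f"sleep column {c!r} missing")

    cov_cols = [c for c in covariates.columns if c != "subject_id"]
    merged = scores.merge(sleep, on="subject_id", how="outer", sort=False).merge(
        covariates, on="subject_id", how="inner", sort=False
    )
    records = []
    for sc in score_cols:
        for sv in sleep_cols:
            sub = merged[[sc, sv] + cov_cols].dropna()
            res = partial_spearman(
                sub[sc].to_numpy(), sub[sv].to_numpy(), sub[cov_cols].to_numpy()
            )
            records.append(
                {
                    "personality_score": sc,
                    "sleep_variable": sv,
                    "rho": res.rho,
                    "p": res.p,
                    "n": res.n,
                }
            )
    return pd.DataFrame(records)


def adjust_pvalues(records: pd.DataFrame, method: str = "bh") -> pd.DataFrame:
    """Correct the grid's p values jointly across all tests (one family)."""
    if method not in _ADJUST_METHODS:
        raise ConfigurationError(f"unknown adjustment method {method!r}")
    out = records.copy()
    _, p_adj, *_ = multipletests(out["p"].to_numpy(), method=_ADJUST_METHODS[method])
    out["p_adj"] = np.maximum(p_adj, out["p"].to_numpy())
    return out


def compare_dependent_correlations(r_xa: float, r_xb: float, r_ab: float, n: int):
    """Steiger's Z for H0: rho_xa = rho_xb with overlapping variable x.

    Fisher-z difference scaled by the covariance of the two dependent
    correlations (average-r form); two-sided p.
    """
    for r in (r_xa, r_xb, r_ab):
        if abs(r) >= 1.0:
            raise DataError("degenerate correlation |r| >= 1")
    if n <= 10:
        raise DataError("compare_dependent_correlations requires n > 10")
    rbar = 0.5 * (r_xa + r_xb)
    cov = (
        r_ab * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r_ab**2)
    ) / (1.0 - rbar**2) ** 2
    z1 = math.atanh(r_xa)
    z2 = math.atanh(r_xb)
    z = (z1 - z2) * math.sqrt((n - 3.0) / (2.0 * (1.0 - cov)))
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, min(p, 1.0)


def extreme_deciles(scores, decile: float = 0.1) -> np.ndarray:
    """Label each subject top / bottom / excluded by nearest-rank deciles.

    The bottom (top) group holds the ``ceil(decile * n)`` lowest
    (highest) scores, extended by all ties at the boundary value, so
    groups may be unequal.
    """
    s = np.asarray(scores, dtype=float)
    n = len(s)
    if n < 20:
        raise DataError("extreme_deciles requires >= 20 subjects")
    m = math.ceil(decile * n)
    srt = np.sort(s)
    low_thr = srt[m - 1]
    high_thr = srt[n - m]
    if low_thr >= high_thr:
        raise DataError("degenerate score distribution: decile thresholds overlap")
    labels = np.full(n, "excluded", dtype=object)
    labels[s <= low_thr] = "bottom"
    labels[s >= high_thr] = "top"
    return labels


def kruskal_wallis(values, groups):
    """Tie-corrected Kruskal-Wallis H and chi-square p value.

    All-identical values give (H=0, p=1) by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = [g for g in pd.unique(groups)]
    if len(uniq) < 2:
        raise DataError("kruskal_wallis requires >= 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise DataError("kruskal_wallis requires nonempty groups")
    if len(np.unique(values)) == 1:
        return 0.0, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), float(p)


def extreme_group_tests(
    score, sleep: pd.DataFrame, sleep_cols=None, decile: float = 0.1
) -> pd.DataFrame:
    """Kruskal-Wallis contrasts of top vs bottom score deciles per variable.

    ``score`` and ``sleep`` must be row-aligned (same subjects).
    """
    sleep_cols = list(sleep_cols or [c for c in sleep.columns if c != "subject_id"])
    labels = extreme_deciles(np.asarray(score, dtype=float), decile=decile)
    sel = labels != "excluded"
    rows = []
    for sv in sleep_cols:
        v = sleep[sv].to_numpy(dtype=float)
        ok = sel & ~np.isnan(v)
        H, p = kruskal_wallis(v[ok], labels[ok])
        top = v[ok & (labels == "top")]
        bot = v[ok & (labels == "bottom")]
        rows.append(
            {
                "sleep_variable": sv,
                "H": H,
                "p": p,
                "n_top": len(top),
                "n_bottom": len(bot),
                "median_top": float(np.median(top)),
                "median_bottom": float(np.median(bot)),
            }
        )
    return pd.DataFrame(rows)
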