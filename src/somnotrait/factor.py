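"""Factor analysis of dichotomous items via tetrachoric correlations.

Pipeline: pairwise maximum-likelihood tetrachoric correlations (with
thresholds fixed at the sample margins, the MLE reduces to matching the
model joint-endorsement probability to the observed cell frequency),
nearest-PSD smoothing by eigenvalue clipping, factor retention by
Horn's parallel analysis, iterated principal-axis extraction, promax
oblique rotation, and Thurstone regression factor scores.

The bivariate normal CDF is evaluated through Owen's T function, which
keeps the per-pair root solve cheap enough to build a full 44 x 44
tetrachoric matrix (and its parallel-analysis null distribution) in
milliseconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.optimize import linear_sum_assignment
from scipy.special import ndtr, ndtri, owens_t

from .errors import ConfigurationError, ConstantInputError, DataError, ExtractionError

logger = logging.getLogger(__name__)

_RHO_CAP = 1.0 - 1e-6


# ---------------------------------------------------------------------------
# bivariate normal CDF (Owen's T identity)
# ---------------------------------------------------------------------------

def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal, vectorized.

    Uses Phi2(h,k,rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - delta
    with Owen's T; near-zero arguments are nudged to avoid the removable
    singularity of a_h at h = 0.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)

    eps = 1e-12
    hs = np.where(np.abs(h) < eps, eps, h)
    ks = np.where(np.abs(k) < eps, eps, k)
    denom = np.sqrt(np.clip(1.0 - rho * rho, 1e-15, None))
    a_h = (ks - rho * hs) / (hs * denom)
    a_k = (hs - rho * ks) / (ks * denom)
    delta = np.where((hs * ks > 0) | ((hs * ks == 0) & (hs + ks >= 0)), 0.0, 0.5)
    out = 0.5 * (ndtr(hs) + ndtr(ks)) - owens_t(hs, a_h) - owens_t(ks, a_k) - delta

    # |rho| -> 1 limits (comonotone / antithetic)
    hi = rho >= 1.0 - 1e-12
    lo = rho <= -1.0 + 1e-12
    if hi.any():
        out = np.where(hi, ndtr(np.minimum(hs, ks)), out)
    if lo.any():
        out = np.where(lo, np.clip(ndtr(hs) + ndtr(ks) - 1.0, 0.0, None), out)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# tetrachoric correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TetrachoricResult:
    rho: float
    corrected: bool   # continuity correction (0.5 added to all cells) applied
    capped: bool      # |rho| hit the 1 - 1e-6 cap


def _cells(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    return np.array([[n00, n01], [n10, n11]], dtype=float)


def tetrachoric(x, y) -> TetrachoricResult:
    """ML tetrachoric correlation from the 2 x 2 table of two binaries.

    Thresholds come from the marginals via the inverse normal; rho then
    maximizes the bivariate-normal multinomial likelihood, which (with
    margins fixed) is the root of Phi2(tau_x, tau_y, rho) = p00.
    A zero cell triggers a continuity correction (0.5 added to all four
    cells), flagged in the result.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if set(np.unique(x)) - {0, 1} or set(np.unique(y)) - {0, 1}:
        raise DataError("tetrachoric requires binary 0/1 vectors")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ConstantInputError("tetrachoric undefined for a constant variable")
    cells = _cells(x, y)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    n = cells.sum()
    p1x = cells[1].sum() / n
    p1y = cells[:, 1].sum() / n
    p00 = cells[0, 0] / n
    tau_x = ndtri(1.0 - p1x)
    tau_y = ndtri(1.0 - p1y)

    def f(r):
        return float(bvn_cdf(tau_x, tau_y, r)) - p00

    lo, hi = -_RHO_CAP, _RHO_CAP
    flo, fhi = f(lo), f(hi)
    if flo >= 0:           # even rho = -1 gives too much (0,0) mass
        return TetrachoricResult(lo, corrected, True)
    if fhi <= 0:
        return TetrachoricResult(hi, corrected, True)
    rho = brentq(f, lo, hi, xtol=1e-10)
    return TetrachoricResult(float(rho), corrected, abs(rho) >= _RHO_CAP - 1e-9)


def tetrachoric_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise tetrachorics of a binary matrix, by vectorized bisection.

    Returns ``(R, corrected)`` where ``corrected[i, j]`` marks pairs that
    needed the zero-cell continuity correction.  Columns must be
    non-constant.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    colsum = X.sum(axis=0)
    if (colsum == 0).any() or (colsum == n).any():
        bad = np.where((colsum == 0) | (colsum == n))[0]
        raise ConstantInputError(f"constant item columns: {bad.tolist()}")

    n11 = X.T @ X
    n10 = colsum[:, None] - n11
    n01 = colsum[None, :] - n11
    n00 = n - n11 - n10 - n01
    iu = np.triu_indices(p, k=1)
    cells = np.stack([n00[iu], n01[iu], n10[iu], n11[iu]], axis=0)
    corrected_u = (cells == 0).any(axis=0)
    cells = cells + 0.5 * corrected_u

    tot = cells.sum(axis=0)
    p1x = (cells[2] + cells[3]) / tot
    p1y = (cells[1] + cells[3]) / tot
    p00 = cells[0] / tot
    tau_x = ndtri(1.0 - p1x)
    tau_y = ndtri(1.0 - p1y)

    lo = np.full(p00.shape, -_RHO_CAP)
    hi = np.full(p00.shape, _RHO_CAP)
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        too_low = bvn_cdf(tau_x, tau_y, mid) < p00
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    rho_u = 0.5 * (lo + hi)

    R = np.eye(p)
    R[iu] = rho_u
    R = R + np.triu(R, k=1).T
    corrected = np.zeros((p, p), dtype=bool)
    corrected[iu] = corrected_u
    corrected |= corrected.T
    return R, corrected


# ---------------------------------------------------------------------------
# PSD smoothing, retention, extraction
# ---------------------------------------------------------------------------

def smooth_to_psd(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Nearest-PSD by eigenvalue clipping at ``eps``, rescaled to unit diagonal.

    A matrix that is already PSD is returned unchanged.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise DataError("smooth_to_psd expects a symmetric matrix")
    w, V = np.linalg.eigh(R)
    if w.min() >= 0.0:
        return R.copy()
    w = np.clip(w, eps, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S


def retain_k(
    R: np.ndarray,
    n: int,
    n_sims: int = 100,
    seed: int = 0,
    thresholds: np.ndarray | None = None,
) -> int:
    """Horn's parallel analysis: count eigenvalues above the null 95th pct.

    The null reference simulates ``n_sims`` datasets of ``n`` independent
    observations.  When ``thresholds`` (per-item dichotomization points)
    are given, null data are dichotomized normals analyzed with the same
    tetrachoric estimator and PSD smoothing as the observed matrix, so
    observed and reference eigenvalues share the estimator's sampling
    noise; otherwise plain Gaussian data with Pearson correlations.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    rng = np.random.default_rng(seed)
    null_eigs = np.empty((n_sims, p))
    for s in range(n_sims):
        Z = rng.standard_normal((n, p))
        if thresholds is None:
            C = np.corrcoef(Z, rowvar=False)
        else:
            B = (Z > np.asarray(thresholds)[None, :]).astype(float)
            # guard against degenerate all-0/all-1 columns at extreme thresholds
            cs = B.sum(axis=0)
            fix = (cs == 0) | (cs == n)
            if fix.any():
                B[0, fix] = 1.0 - B[0, fix]
            C, _ = tetrachoric_matrix(B)
            C = smooth_to_psd(C)
        null_eigs[s] = np.linalg.eigvalsh(C)[::-1]
    ref = np.percentile(null_eigs, 95, axis=0)
    obs = np.linalg.eigvalsh(R)[::-1]
    exceeds = obs > ref
    k = 0
    while k < p and exceeds[k]:   # leading consecutive eigenvalues only
        k += 1
    return k


def extract(R: np.ndarray, k: int, tol: float = 1e-6, max_iter: int = 1000) -> np.ndarray:
    """Iterated principal-axis factoring: items x k unrotated loadings.

    Communalities start at squared multiple correlations and iterate to
    convergence; Heywood communalities are clipped to 1 and logged.
    Columns are ordered by explained variance.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if k < 1:
        raise ConfigurationError("extract requires k >= 1")
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        h2 = np.max(np.abs(R - np.eye(p)), axis=0)
    h2 = np.clip(h2, 0.0, 1.0)

    trace = []
    for it in range(max_iter):
        Rh = R.copy()
        np.fill_diagonal(Rh, h2)
        w, V = np.linalg.eigh(Rh)
        w, V = w[::-1][:k], V[:, ::-1][:, :k]
        lam = V * np.sqrt(np.clip(w, 0.0, None))
        h2_new = np.sum(lam**2, axis=1)
        if (h2_new > 1.0).any():
            logger.warning("Heywood case: %d communalities clipped to 1", int((h2_new > 1).sum()))
            h2_new = np.clip(h2_new, 0.0, 1.0)
        delta = float(np.max(np.abs(h2_new - h2)))
        trace.append(delta)
        h2 = h2_new
        if delta < tol:
            return lam
    raise ExtractionError(
        f"principal-axis iteration did not converge in {max_iter} steps", trace=trace
    )


# ---------------------------------------------------------------------------
# rotation and scores
# ---------------------------------------------------------------------------

@dataclass
class FactorSolution:
    """Oblique factor solution with interpretation metadata."""

    loadings: np.ndarray            # items x k pattern loadings
    factor_corr: np.ndarray         # k x k
    k: int
    rotation: str
    communalities: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)
    item_names: list[str] = field(default_factory=list)

    @property
    def structure(self) -> np.ndarray:
        return self.loadings @ self.factor_corr


def varimax(A: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser-normalized varimax; returns rotated loadings and rotation R."""
    A = np.asarray(A, dtype=float)
    p, k = A.shape
    h = np.sqrt(np.sum(A**2, axis=1))
    h[h == 0] = 1.0
    An = A / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        L = An @ R
        U, s, Vt = np.linalg.svd(An.T @ (L**3 - L @ np.diag(np.sum(L**2, axis=0)) / p))
        R = U @ Vt
        d_new = s.sum()
        if d_new <= d * (1.0 + tol):
            break
        d = d_new
    return (An @ R) * h[:, None], R


def rotate_oblique(loadings: np.ndarray, power: int = 4) -> FactorSolution:
    """Promax rotation: varimax, then a least-squares oblique transform
    toward the element-wise power-``power`` target.

    Column signs are fixed so each factor's largest-magnitude loading is
    positive; columns are ordered by sum of squared pattern loadings.
    """
    A = np.asarray(loadings, dtype=float)
    p, k = A.shape
    if k == 1:
        return FactorSolution(
            loadings=A.copy(),
            factor_corr=np.array([[1.0]]),
            k=1,
            rotation="identity",
            communalities=np.sum(A**2, axis=1),
        )
    V, R = varimax(A)
    target = V * np.abs(V) ** (power - 1)
    G = V.T @ V
    if np.linalg.cond(G) > 1e12:
        raise ExtractionError("promax transformation is singular")
    Q = np.linalg.solve(G, V.T @ target)
    U = R @ Q
    UtU = U.T @ U
    if np.linalg.cond(UtU) > 1e12:
        raise ExtractionError("promax transformation is singular")
    phi0 = np.linalg.inv(UtU)
    d = np.sqrt(np.diag(phi0))
    phi = phi0 / np.outer(d, d)
    pattern = (A @ U) * d[None, :]

    # sign convention, then order by explained variance
    for j in range(k):
        if pattern[np.argmax(np.abs(pattern[:, j])), j] < 0:
            pattern[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
    order = np.argsort(-np.sum(pattern**2, axis=0), kind="stable")
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    np.fill_diagonal(phi, 1.0)

    comm = np.sum((pattern @ phi) * pattern, axis=1)
    return FactorSolution(
        loadings=pattern,
        factor_corr=phi,
        k=k,
        rotation="promax",
        communalities=comm,
    )


def label_factors(
    solution: FactorSolution, marker_items: dict[str, list[str]], item_names: list[str]
) -> dict[int, str]:
    """Assign subscale labels to factors via configured marker-item lists.

    Each label goes to the factor with the highest mean structure
    loading over its markers, as a one-to-one assignment.  Falls back to
    explained-variance order if no markers are given.
    """
    k = solution.k
    names = list(marker_items)
    if not names:
        return {j: f"factor_{j + 1}" for j in range(k)}
    idx = {it: i for i, it in enumerate(item_names)}
    S = solution.structure
    score = np.zeros((len(names), k))
    for a, lab in enumerate(names):
        rows = [idx[i] for i in marker_items[lab] if i in idx]
        if not rows:
            raise ConfigurationError(f"no marker items of {lab!r} present")
        score[a] = np.mean(S[rows], axis=0)
    rr, cc = linear_sum_assignment(-score)
    labels = {int(c): names[r] for r, c in zip(rr, cc)}
    for j in range(k):
        labels.setdefault(j, f"factor_{j + 1}")
    return labels


def factor_scores(
    responses: pd.DataFrame,
    solution: FactorSolution,
    R: np.ndarray,
    item_names: list[str] | None = None,
) -> pd.DataFrame:
    """Thurstone regression factor scores, standardized per column.

    ``scores = Z R^{-1} (Lambda Phi)`` with Z the standardized item
    matrix; columns are named after the solution's factor labels.
    Subjects with missing responses are excluded.
    """
    items = item_names or solution.item_names
    if not items:
        raise ConfigurationError("factor_scores needs the fitted item order")
    X = responses[items]
    complete = X.notna().all(axis=1).to_numpy()
    if (~complete).sum():
        logger.info("excluding %d subjects with incomplete responses", int((~complete).sum()))
    V = X[complete].to_numpy(dtype=float)
    mu = V.mean(axis=0)
    sd = V.std(axis=0)
    if (sd == 0).any():
        raise ConstantInputError("constant item column; factor scores undefined")
    Z = (V - mu) / sd
    W = np.linalg.solve(R, solution.structure)
    S = Z @ W
    S = (S - S.mean(axis=0)) / S.std(axis=0)

    out = pd.DataFrame({"subject_id": responses.loc[complete, "subject_id"].to_numpy()})
    for j in range(solution.k):
        name = solution.labels.get(j, f"factor_{j + 1}")
        out[f"score_{name}"] = S[:, j]
    return out


# ---------------------------------------------------------------------------
# convenience: full HPS factor pipeline
# ---------------------------------------------------------------------------

def fit_hps_factors(
    responses: pd.DataFrame,
    k: int | None = None,
    n_sims: int = 100,
    seed: int = 0,
    marker_items: dict[str, list[str]] | None = None,
) -> tuple[FactorSolution, pd.DataFrame]:
    """Tetrachoric FA of an item response table; returns solution + scores.

    ``k=None`` retains by parallel analysis (tetrachoric null reference
    at the observed item margins).
    """
    item_names = [c for c in responses.columns if c != "subject_id"]
    X = responses[item_names].to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    X = X[complete]
    R_raw, _ = tetrachoric_matrix(X)
    R = smooth_to_psd(R_raw)
    if k is None:
        taus = ndtri(1.0 - X.mean(axis=0))
        k = retain_k(R, n=X.shape[0], n_sims=n_sims, seed=seed, thresholds=taus)
        if k < 1:
            raise ExtractionError("parallel analysis retained no factors")
    lam = extract(R, k)
    solution = rotate_oblique(lam)
    solution.item_names = item_names
    if marker_items:
        solution.labels = label_factors(solution, marker_items, item_names)
    scores = factor_scores(responses, solution, R, item_names)
    return solution, scores
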