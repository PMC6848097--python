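"""Cross-validated incremental prediction of personality scores.

Contrasts an OLS model with covariates only (age, sex, socioeconomic
status, BMI when present) against covariates plus the sleep panel,
under a shared seeded k-fold partition.  Predictors are standardized on
each training fold only (no leakage); out-of-sample R-squared pools all
held-out predictions as ``1 - SSE/SST`` with SST about the full-sample
mean of the target, which is stable with small folds.  The incremental
value is the difference of the two out-of-sample R-squared values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)


@dataclass
class CvResult:
    target: str
    r2_base: float
    r2_full: float
    incremental: float
    folds: np.ndarray
    seed: int | None = None


def kfold_assign(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Seeded random partition into k folds with sizes differing by <= 1."""
    if k < 2:
        raise ConfigurationError("kfold_assign requires k >= 2")
    if n < k:
        raise DataError(f"need n >= k, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    start = 0
    for f in range(k):
        size = n // k + (1 if f < n % k else 0)
        labels[perm[start : start + size]] = f
        start += size
    return labels


def _oos_predictions(y: np.ndarray, X: np.ndarray, folds: np.ndarray) -> np.ndarray:
    """Pooled held-out OLS predictions with per-fold standardization."""
    n, p = X.shape
    pred = np.empty(n)
    for f in np.unique(folds):
        tr = folds != f
        te = ~tr
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = np.column_stack([np.ones(tr.sum()), (X[tr] - mu) / sd])
        Xte = np.column_stack([np.ones(te.sum()), (X[te] - mu) / sd])
        if np.linalg.matrix_rank(Xtr) < Xtr.shape[1]:
            logger.info("rank-deficient training design in fold %d; using min-norm fit", f)
        beta, *_ = np.linalg.lstsq(Xtr, y[tr], rcond=None)
        pred[te] = Xte @ beta
    return pred


def cv_incremental_r2(
    y,
    base_predictors,
    extra_predictors,
    folds,
    target: str = "target",
    seed: int | None = None,
) -> CvResult:
    """Out-of-sample incremental R-squared of extra predictors over a base set.

    Both models use identical folds; SST is about the full-sample mean
    of ``y`` so fold-level R-squared instability does not propagate.
    """
    y = np.asarray(y, dtype=float)
    B = np.asarray(base_predictors, dtype=float)
    E = np.asarray(extra_predictors, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    if E.ndim == 1:
        E = E[:, None]
    folds = np.asarray(folds)
    if not (len(y) == len(B) == len(E) == len(folds)):
        raise DataError("y, predictors and folds must be row-aligned")
    if np.isnan(y).any() or np.isnan(B).any() or np.isnan(E).any():
        raise DataError("cv_incremental_r2 requires complete cases")

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise DataError("target variable is constant")
    pred_base = _oos_predictions(y, B, folds)
    pred_full = _oos_predictions(y, np.column_stack([B, E]), folds)
    r2_base = 1.0 - float(np.sum((y - pred_base) ** 2)) / sst
    r2_full = 1.0 - float(np.sum((y - pred_full) ** 2)) / sst
    return CvResult(
        target=target,
        r2_base=r2_base,
        r2_full=r2_full,
        incremental=r2_full - r2_base,
        folds=folds,
        seed=seed,
    )
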