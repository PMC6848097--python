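"""Factor-analysis tests: tetrachorics, smoothing, retention, rotation, scores."""

import numpy as np
import pandas as pd
import pytest

from somnotrait import (
    CohortConfig,
    extract,
    factor_scores,
    fit_hps_factors,
    generate_item_responses,
    generate_subjects,
    retain_k,
    rotate_oblique,
    smooth_to_psd,
    tetrachoric,
    tetrachoric_matrix,
)
from somnotrait.errors import ConstantInputError

from oracles import tetrachoric_brute


def _markers(cfg):
    return {
        s: [i.item for i in cfg.items if i.factor == s]
        for s in ("core", "vitality", "ordinariness")
    }


@pytest.fixture(scope="module")
def fitted(small_cohort_module):
    cfg, tabs = small_cohort_module
    return fit_hps_factors(tabs["hps_items"], k=3, marker_items=_markers(cfg))


@pytest.fixture(scope="module")
def small_cohort_module():
    cfg = CohortConfig.default(seed=0, n_subjects=1200)
    subs = generate_subjects(cfg)
    return cfg, {"hps_items": generate_item_responses(subs, cfg), "subjects": subs}


class TestTetrachoric:
    def test_independence_gives_zero(self, rng):
        x = (rng.random(20_000) < 0.4).astype(int)
        y = (rng.random(20_000) < 0.6).astype(int)
        assert abs(tetrachoric(x, y).rho) < 0.03

    def test_perfect_concordance_near_one_and_flagged(self):
        x = np.array([0] * 50 + [1] * 50)
        res = tetrachoric(x, x.copy())
        assert 0.99 < res.rho < 1.0
        assert res.corrected

    def test_dichotomized_bivariate_normal_recovery(self):
        rng = np.random.default_rng(42)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=100_000)
        x = (z[:, 0] > 0).astype(int)
        y = (z[:, 1] > 0).astype(int)
        assert abs(tetrachoric(x, y).rho - 0.5) < 0.02

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            tetrachoric(np.ones(50, dtype=int), np.array([0, 1] * 25))

    def test_scalar_and_matrix_paths_agree_with_ml_oracle(self, rng):
        from somnotrait.factor import _cells

        for _ in range(25):
            n = int(rng.integers(60, 400))
            r = rng.uniform(-0.8, 0.8)
            z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
            x = (z[:, 0] > rng.normal(0, 0.5)).astype(int)
            y = (z[:, 1] > rng.normal(0, 0.5)).astype(int)
            if x.min() == x.max() or y.min() == y.max():
                continue
            mine = tetrachoric(x, y).rho
            R, _ = tetrachoric_matrix(np.column_stack([x, y]))
            oracle = tetrachoric_brute(_cells(x, y))
            assert mine == pytest.approx(oracle, abs=2e-3)
            assert R[0, 1] == pytest.approx(mine, abs=1e-6)


class TestSmoothToPsd:
    def test_identity_unchanged(self):
        assert np.array_equal(smooth_to_psd(np.eye(4)), np.eye(4))

    def test_psd_input_is_noop(self, rng):
        A = rng.standard_normal((6, 6))
        R = A @ A.T + 6 * np.eye(6)
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        assert np.abs(smooth_to_psd(R) - R).max() < 1e-12

    def test_indefinite_input_repaired(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(R).min() < 0
        S = smooth_to_psd(R)
        assert np.linalg.eigvalsh(S).min() >= 0
        assert np.allclose(np.diag(S), 1.0)
        assert np.allclose(S, S.T)


class TestRetainK:
    def test_identity_retains_nothing(self):
        for seed in (0, 1, 2):
            assert retain_k(np.eye(10), n=2000, seed=seed) <= 1

    def test_single_factor_structure(self):
        R = np.full((10, 10), 0.5)
        np.fill_diagonal(R, 1.0)
        assert retain_k(R, n=2000, seed=0) == 1

    def test_three_factor_cohort_retains_three(self, small_cohort_module):
        cfg, tabs = small_cohort_module
        sol, _ = fit_hps_factors(tabs["hps_items"], k=None, seed=5, marker_items=_markers(cfg))
        assert sol.k == 3


class TestExtract:
    def test_identity_gives_null_loadings(self):
        lam = extract(np.eye(8), 1)
        assert np.abs(lam).max() < 1e-4

    def test_rank_one_closed_form(self):
        lam = np.full(6, 0.8)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        est = extract(R, 1)
        assert np.abs(np.abs(est[:, 0]) - 0.8).max() < 1e-3

    def test_model_reproduces_correlation_matrix(self, small_cohort_module, fitted):
        cfg, tabs = small_cohort_module
        X = tabs["hps_items"].drop(columns="subject_id").to_numpy(float)
        R = smooth_to_psd(tetrachoric_matrix(X)[0])
        sol = fitted[0]
        implied = sol.loadings @ sol.factor_corr @ sol.loadings.T
        resid = R - implied
        np.fill_diagonal(resid, 0.0)
        p = R.shape[0]
        rmsr = np.sqrt((resid**2).sum() / (p * (p - 1)))
        assert rmsr < 0.05


class TestRotation:
    def test_single_factor_identity(self):
        lam = np.linspace(0.3, 0.8, 6)[:, None]
        sol = rotate_oblique(lam)
        assert sol.rotation == "identity"
        assert np.array_equal(sol.loadings, lam)

    def test_orthogonal_simple_structure_stays_orthogonal(self):
        A = np.zeros((12, 3))
        A[:4, 0] = [0.8, 0.7, 0.65, 0.6]
        A[4:8, 1] = [0.75, 0.7, 0.6, 0.55]
        A[8:, 2] = [0.7, 0.65, 0.6, 0.7]
        R = A @ A.T
        np.fill_diagonal(R, 1.0)
        sol = rotate_oblique(extract(R, 3))
        off = sol.factor_corr[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_sign_convention(self, fitted):
        sol = fitted[0]
        for j in range(sol.k):
            assert sol.loadings[np.argmax(np.abs(sol.loadings[:, j])), j] > 0

    def test_congruence_with_generating_blocks(self, small_cohort_module, fitted):
        cfg, _ = small_cohort_module
        sol = fitted[0]
        inv_labels = {v: k for k, v in sol.labels.items()}
        items = list(sol.item_names)
        for facname in ("core", "vitality", "ordinariness"):
            rows = [items.index(i.item) for i in cfg.items if i.factor == facname]
            gen = np.array([i.loading for i in cfg.items if i.factor == facname])
            est = sol.loadings[rows, inv_labels[facname]]
            congruence = gen @ est / np.sqrt((gen @ gen) * (est @ est))
            assert congruence > 0.95


class TestFactorScores:
    def test_standardization(self, fitted):
        _, scores = fitted
        S = scores.drop(columns="subject_id").to_numpy()
        assert np.abs(S.mean(axis=0)).max() < 1e-6
        assert np.abs(S.std(axis=0) - 1).max() < 0.05

    def test_truth_recovery(self, small_cohort_module, fitted):
        _, tabs = small_cohort_module
        m = tabs["subjects"].merge(fitted[1], on="subject_id")
        for f in ("core", "vitality", "ordinariness"):
            assert np.corrcoef(m[f"latent_{f}"], m[f"score_{f}"])[0, 1] > 0.8

    def test_item_order_invariance(self, small_cohort_module):
        cfg, tabs = small_cohort_module
        items = tabs["hps_items"]
        perm_cols = ["subject_id"] + list(np.random.default_rng(1).permutation(
            [c for c in items.columns if c != "subject_id"]
        ))
        sol_a, sc_a = fit_hps_factors(items, k=3, marker_items=_markers(cfg))
        sol_b, sc_b = fit_hps_factors(items[perm_cols], k=3, marker_items=_markers(cfg))
        for col in ("score_core", "score_vitality", "score_ordinariness"):
            assert np.abs(sc_a[col].to_numpy() - sc_b[col].to_numpy()).max() < 1e-8

    def test_sum_scores_attenuated_relative_to_factor_scores(self):
        # unweighted sums carry item noise, so their cross-domain
        # associations are comparable but somewhat weaker
        from somnotrait import analyze_cohort, generate_cohort, partial_spearman

        cfg = CohortConfig.default(seed=21, n_subjects=5000, n_actigraphy=5000, n_psqi=5000)
        tabs = generate_cohort(cfg)
        at = analyze_cohort(tabs, cfg, k_factors=3)
        m = at.scores.merge(at.sleep, on="subject_id").merge(at.covariates, on="subject_id")
        cov = m[["age", "sex"]].to_numpy()
        for var in ("isd_waso", "psqi_total"):
            sub = m.dropna(subset=[var])
            r_factor = partial_spearman(sub["score_core"], sub[var], cov[sub.index]).rho
            r_sum = partial_spearman(sub["sum_core"], sub[var], cov[sub.index]).rho
            assert abs(r_sum) <= abs(r_factor) + 0.02
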