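"""Association-statistics tests: partial Spearman, grid, BH, Steiger, deciles, KW."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnotrait import (
    adjust_pvalues,
    compare_dependent_correlations,
    correlate_grid,
    extreme_deciles,
    kruskal_wallis,
    partial_spearman,
)
from somnotrait.errors import DataError

from oracles import bh_brute, kruskal_brute, partial_spearman_brute


class TestPartialSpearman:
    def test_monotone_relation_with_constant_covariate(self):
        x = np.arange(1, 11, dtype=float)
        res = partial_spearman(x, x**2, np.ones((10, 1)))
        assert res.rho == pytest.approx(1.0)

    def test_matches_independent_composition_oracle(self, rng):
        for _ in range(100):
            n = 30
            x = rng.standard_normal(n)
            y = 0.3 * x + rng.standard_normal(n)
            C = rng.standard_normal((n, 2))
            res = partial_spearman(x, y, C)
            rho_o, p_o = partial_spearman_brute(x, y, C)
            assert res.rho == pytest.approx(rho_o, abs=1e-10)
            assert res.p == pytest.approx(p_o, abs=1e-10)

    def test_type_one_error_when_covariate_drives_y(self):
        # y = age + noise, x independent of y given age
        rng = np.random.default_rng(0)
        n, reps = 771, 2000
        rejections = 0
        age = rng.uniform(60, 82, n)
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = 0.05 * age + rng.standard_normal(n)
            if partial_spearman(x, y, age[:, None]).p < 0.05:
                rejections += 1
        rate = rejections / reps
        half = 2.576 * math.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half <= rate <= 0.05 + half

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariance_under_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(40)
        y = r.standard_normal(40)
        C = r.standard_normal((40, 1))
        a = partial_spearman(x, y, C)
        b = partial_spearman(np.exp(x), y**3, C)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_constant_covariate_dropped(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        C = np.column_stack([np.ones(50), rng.standard_normal(50)])
        res = partial_spearman(x, y, C)
        ref = partial_spearman(x, y, C[:, 1:])
        assert res.rho == pytest.approx(ref.rho)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(5)
    n = 120
    ids = [f"S{i}" for i in range(n)]
    scores = pd.DataFrame({"subject_id": ids, "a": rng.standard_normal(n),
                           "b": rng.standard_normal(n)})
    sleep = pd.DataFrame({"subject_id": ids,
                          "v1": rng.standard_normal(n),
                          "v2": rng.standard_normal(n)})
    cov = pd.DataFrame({"subject_id": ids, "age": rng.uniform(60, 82, n),
                        "sex": rng.integers(0, 2, n)})
    return scores, sleep, cov


class TestCorrelateGrid:
    def test_full_study_panel_gives_84_records(self, small_analysis):
        from somnotrait import SCORE_COLUMNS, SLEEP_PANEL

        grid = correlate_grid(
            small_analysis.scores, small_analysis.sleep, small_analysis.covariates,
            score_cols=list(SCORE_COLUMNS), sleep_cols=list(SLEEP_PANEL),
        )
        assert len(grid) == 84
        assert grid[["personality_score", "sleep_variable"]].drop_duplicates().shape[0] == 84
        assert grid["rho"].between(-1, 1).all()
        assert grid["p"].between(0, 1).all()

    def test_single_pair_reduces_to_partial_spearman(self, toy):
        scores, sleep, cov = toy
        grid = correlate_grid(scores, sleep, cov, score_cols=["a"], sleep_cols=["v1"])
        direct = partial_spearman(
            scores["a"], sleep["v1"], cov[["age", "sex"]].to_numpy()
        )
        assert len(grid) == 1
        assert grid["rho"].iloc[0] == pytest.approx(direct.rho)
        assert grid["p"].iloc[0] == pytest.approx(direct.p)
        assert grid["n"].iloc[0] == direct.n

    def test_duplicated_sleep_column_gives_identical_records(self, toy):
        scores, sleep, cov = toy
        sleep = sleep.assign(v1_copy=sleep["v1"])
        grid = correlate_grid(scores, sleep, cov, score_cols=["a"],
                              sleep_cols=["v1", "v1_copy"])
        assert grid["rho"].iloc[0] == grid["rho"].iloc[1]
        assert grid["p"].iloc[0] == grid["p"].iloc[1]


class TestAdjustPvalues:
    def test_bh_hand_applied_step_up(self):
        df = pd.DataFrame({"p": [0.01, 0.02, 0.04, 0.8]})
        out = adjust_pvalues(df, "bh")
        assert out["p_adj"].tolist() == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_ties_at_same_rank(self):
        df = pd.DataFrame({"p": [0.01] * 84})
        out = adjust_pvalues(df, "bh")
        assert out["p_adj"].tolist() == pytest.approx([0.01] * 84)

    def test_single_test_unchanged(self):
        assert adjust_pvalues(pd.DataFrame({"p": [0.3]}), "bh")["p_adj"].iloc[0] == 0.3

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, size=rng.integers(2, 50))
            out = adjust_pvalues(pd.DataFrame({"p": p}), "bh")["p_adj"].to_numpy()
            assert out == pytest.approx(np.array(bh_brute(list(p))), abs=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        for method in ("bh", "holm", "bonferroni"):
            p = rng.uniform(0, 1, 30)
            out = adjust_pvalues(pd.DataFrame({"p": p}), method)
            assert (out["p_adj"] >= out["p"] - 1e-15).all()


class TestSteigerZ:
    def test_equal_correlations_give_null(self):
        z, p = compare_dependent_correlations(0.3, 0.3, 0.5, 500)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        z1, _ = compare_dependent_correlations(0.3, 0.1, 0.7, 1766)
        z2, _ = compare_dependent_correlations(0.1, 0.3, 0.7, 1766)
        assert z1 == pytest.approx(-z2)

    def test_against_monte_carlo_null(self):
        # simulate the null: rho_xa = rho_xb = 0.2, r_ab = 0.7; compare the
        # analytic tail probability of the observed Fisher-z difference
        # with its Monte Carlo frequency
        n, sims = 1766, 40_000
        rng = np.random.default_rng(3)
        S = np.array([[1.0, 0.2, 0.2], [0.2, 1.0, 0.7], [0.2, 0.7, 1.0]])
        L = np.linalg.cholesky(S)
        diffs = np.empty(sims)
        batch = 2000
        for b in range(sims // batch):
            Z = rng.standard_normal((batch, n, 3)) @ L.T
            Zc = Z - Z.mean(axis=1, keepdims=True)
            sd = Zc.std(axis=1)
            r_xa = np.einsum("bn,bn->b", Zc[:, :, 0], Zc[:, :, 1]) / (n * sd[:, 0] * sd[:, 1])
            r_xb = np.einsum("bn,bn->b", Zc[:, :, 0], Zc[:, :, 2]) / (n * sd[:, 0] * sd[:, 2])
            diffs[b * batch:(b + 1) * batch] = np.arctanh(r_xa) - np.arctanh(r_xb)
        z_obs, p_analytic = compare_dependent_correlations(0.3, 0.1, 0.7, n)
        d_obs = math.atanh(0.3) - math.atanh(0.1)
        p_mc = float((np.abs(diffs) >= d_obs).mean())
        assert p_analytic == pytest.approx(p_mc, rel=0.10)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(DataError):
            compare_dependent_correlations(1.0, 0.3, 0.2, 100)


class TestExtremeDeciles:
    def test_exact_deciles(self):
        labels = extreme_deciles(np.arange(1, 101, dtype=float))
        scores = np.arange(1, 101)
        assert set(scores[labels == "bottom"]) == set(range(1, 11))
        assert set(scores[labels == "top"]) == set(range(91, 101))

    def test_boundary_ties_all_included(self):
        s = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9] + [50] * 30 + [90] * 11)
        labels = extreme_deciles(s.astype(float))
        assert (labels[s == 90] == "top").all()

    def test_synthetic_integer_scores_group_sizes(self, small_analysis):
        m = small_analysis.scores.dropna(subset=["hps_total"])
        labels = extreme_deciles(m["hps_total"].to_numpy())
        n = len(m)
        expected = math.ceil(0.1 * n)
        for g in ("top", "bottom"):
            size = (labels == g).sum()
            assert expected <= size <= expected + 40

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(DataError):
            extreme_deciles(np.ones(100))


class TestKruskalWallis:
    def test_rank_sum_formula_example(self):
        H, p = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert H == pytest.approx(12 / 42 * (6**2 / 3 + 15**2 / 3) - 21)
        assert H == pytest.approx(3.857142857, abs=1e-6)

    def test_identical_multisets_give_zero(self):
        H, _ = kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert H == pytest.approx(0.0, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self, rng):
        v = rng.standard_normal(60)
        g = rng.choice(["a", "b", "c"], 60)
        H1, _ = kruskal_wallis(v, g)
        H2, _ = kruskal_wallis(np.exp(v), g)
        assert H1 == pytest.approx(H2, abs=1e-10)

    def test_all_identical_values_convention(self):
        H, p = kruskal_wallis(np.ones(20), ["a"] * 10 + ["b"] * 10)
        assert (H, p) == (0.0, 1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            v = np.round(rng.standard_normal(n), 1)  # induce ties
            g = rng.choice(["a", "b", "c"], n)
            if len(set(g)) < 2 or len(set(v)) < 2:
                continue
            H, p = kruskal_wallis(v, g)
            Ho, po = kruskal_brute(list(v), list(g))
            assert H == pytest.approx(Ho, abs=1e-8)
            assert p == pytest.approx(po, abs=1e-8)
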