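"""Generator tests: determinism, configured structure, null behavior."""

import numpy as np
import pandas as pd
import pytest

from somnotrait import (
    CohortConfig,
    generate_cohort,
    generate_item_responses,
    generate_nights,
    generate_psqi,
    generate_subjects,
    partial_spearman,
    summarize_cohort,
)
from somnotrait.config import ItemSpec
from somnotrait.factor import tetrachoric_matrix
from somnotrait.synthetic import true_night_sds


def _cfg(**kw):
    return CohortConfig.default(**kw)


class TestConfigValidation:
    def test_non_pd_factor_corr_rejected(self):
        bad = [[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]]
        with pytest.raises(ValueError):
            CohortConfig.default(factor_corr=bad)

    def test_nights_dist_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortConfig.default(nights_dist={5: 0.5, 6: 0.2, 7: 0.2})

    def test_loading_out_of_range_rejected(self):
        items = list(CohortConfig.default().items)
        items[0] = ItemSpec(item="q01", factor="core", loading=1.0, threshold=0.5,
                            keyed_positive=True)
        with pytest.raises(ValueError):
            CohortConfig.default(items=tuple(items))


class TestSubjects:
    def test_seeded_determinism(self):
        a = generate_subjects(_cfg(seed=3, n_subjects=500))
        b = generate_subjects(_cfg(seed=3, n_subjects=500))
        pd.testing.assert_frame_equal(a, b)

    def test_shape_and_invariants(self):
        cfg = _cfg(seed=1, n_subjects=2000, n_actigraphy=500, n_psqi=1500)
        s = generate_subjects(cfg)
        assert len(s) == 2000
        assert s["subject_id"].is_unique
        assert s["age"].between(*cfg.age_range).all()
        assert set(s["sex"].unique()) <= {0, 1}
        assert s["has_actigraphy"].sum() == 500
        assert s["has_psqi"].sum() == 1500
        lat = s[["latent_core", "latent_vitality", "latent_ordinariness"]]
        assert np.abs(lat.mean()).max() < 0.1
        assert np.abs(lat.std() - 1).max() < 0.1

    def test_identity_factor_corr_gives_independent_latents(self):
        cfg = _cfg(seed=2, n_subjects=50_000, factor_corr=np.eye(3).tolist())
        s = generate_subjects(cfg)
        C = np.corrcoef(
            s[["latent_core", "latent_vitality", "latent_ordinariness"]].to_numpy().T
        )
        assert np.abs(C - np.eye(3)).max() < 0.02

    def test_configured_latent_correlation_recovered(self):
        cfg = _cfg(seed=2, n_subjects=50_000)
        s = generate_subjects(cfg)
        r = np.corrcoef(s["latent_core"], s["latent_vitality"])[0, 1]
        assert abs(r - 0.4) < 0.02


class TestItems:
    def test_null_model_means_and_tetrachorics(self):
        # all loadings zero, threshold zero: independent fair coins
        items = tuple(
            ItemSpec(item=f"q{i + 1:02d}", factor="core", loading=0.0, threshold=0.0,
                     keyed_positive=True)
            for i in range(44)
        )
        cfg = _cfg(seed=4, n_subjects=50_000, items=items)
        resp = generate_item_responses(generate_subjects(cfg), cfg)
        X = resp.drop(columns="subject_id").to_numpy(float)
        assert np.abs(X.mean(axis=0) - 0.5).max() < 0.02
        R, _ = tetrachoric_matrix(X[:, :10])
        assert np.abs(R - np.eye(10)).max() < 0.03

    def test_implied_tetrachoric_closed_form(self):
        # two items on the same factor with loadings 0.8 -> rho = 0.64
        items = list(_cfg().items)
        items[0] = ItemSpec(item="q01", factor="core", loading=0.8, threshold=0.2,
                            keyed_positive=True)
        items[1] = ItemSpec(item="q02", factor="core", loading=0.8, threshold=-0.3,
                            keyed_positive=True)
        cfg = _cfg(seed=5, n_subjects=50_000, items=tuple(items))
        resp = generate_item_responses(generate_subjects(cfg), cfg)
        R, _ = tetrachoric_matrix(resp[["q01", "q02"]].to_numpy(float))
        assert abs(R[0, 1] - 0.64) < 0.03

    def test_extreme_threshold_gives_all_zero(self):
        items = tuple(
            ItemSpec(item=f"q{i + 1:02d}", factor="core", loading=0.5, threshold=20.0,
                     keyed_positive=True)
            for i in range(44)
        )
        cfg = _cfg(seed=6, n_subjects=200, items=items)
        resp = generate_item_responses(generate_subjects(cfg), cfg)
        assert resp.drop(columns="subject_id").to_numpy().sum() == 0


class TestNights:
    def test_point_mass_nights_dist(self):
        cfg = _cfg(seed=7, n_subjects=300, n_actigraphy=300, nights_dist={7: 1.0})
        nights = generate_nights(generate_subjects(cfg), cfg)
        assert (nights.groupby("subject_id").size() == 7).all()

    def test_mean_nights_matches_study_conditions(self):
        cfg = _cfg(seed=8, n_subjects=10_000, n_actigraphy=10_000)
        nights = generate_nights(generate_subjects(cfg), cfg)
        assert abs(nights.groupby("subject_id").size().mean() - 6.9) < 0.05

    def test_null_variability_effects_decouple_core_from_sigma(self):
        cfg = CohortConfig.null(seed=9, n_subjects=20_000, n_actigraphy=20_000)
        subs = generate_subjects(cfg)
        sig = true_night_sds(subs, cfg)
        m = subs.merge(sig, on="subject_id")
        for col in [c for c in sig.columns if c != "subject_id"]:
            if m[col].nunique() == 1:
                continue  # no trait effect and no covariate effect: constant
            r = partial_spearman(m["latent_core"], m[col]).rho
            assert abs(r) < 0.03, col

    def test_core_effect_on_duration_isd_recovered(self):
        # oracle: large-n Monte Carlo population value
        def rho_at(n, seed):
            cfg = _cfg(seed=seed, n_subjects=n, n_actigraphy=n)
            subs = generate_subjects(cfg)
            m = subs.merge(summarize_cohort(generate_nights(subs, cfg)), on="subject_id")
            return partial_spearman(
                m["latent_core"], m["isd_sleep_duration"], m[["age", "sex"]].to_numpy()
            ).rho

        oracle = rho_at(50_000, seed=100)
        est = rho_at(20_000, seed=101)
        assert est > 0
        assert abs(est - oracle) < 0.03

    def test_night_invariants(self, small_cohort):
        nights = small_cohort["nights"]
        assert (nights["sleep_duration"] > 0).all()
        assert (nights["waso"] >= 0).all()
        assert (nights["sleep_onset_latency"] >= 0).all()
        assert (nights["nwak"] >= 0).all()
        assert nights["nwak"].dtype.kind == "i"
        assert nights.groupby("subject_id").size().between(5, 7).all()


class TestPsqi:
    def test_seeded_determinism(self):
        cfg = _cfg(seed=11, n_subjects=500, n_psqi=400)
        s = generate_subjects(cfg)
        pd.testing.assert_frame_equal(generate_psqi(s, cfg), generate_psqi(s, cfg))

    def test_null_psqi_effects_give_no_association(self):
        cfg = CohortConfig.null(seed=12, n_subjects=50_000, n_psqi=50_000)
        subs = generate_subjects(cfg)
        psqi = generate_psqi(subs, cfg)
        from somnotrait import score_psqi

        scored = score_psqi(psqi).merge(subs, on="subject_id")
        r = partial_spearman(scored["latent_core"], scored["psqi_total"]).rho
        assert abs(r) < 0.02

    def test_negative_core_duration_effect_sign(self):
        cfg = _cfg(seed=13, n_subjects=20_000, n_psqi=20_000)
        subs = generate_subjects(cfg)
        psqi = generate_psqi(subs, cfg)
        m = psqi.merge(subs, on="subject_id")
        r = partial_spearman(m["latent_core"], m["duration_h"],
                             m[["age", "sex"]].to_numpy()).rho
        assert r < 0


class TestCohortDeterminism:
    def test_full_cohort_reproducible(self, small_config, small_cohort):
        again = generate_cohort(small_config)
        for name, df in small_cohort.items():
            pd.testing.assert_frame_equal(df, again[name])
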