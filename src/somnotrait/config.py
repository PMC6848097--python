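"""Cohort configuration, default study conditions, and seed management.

The :class:`CohortConfig` collects every tunable of the synthetic cohort
generator: demographic composition, the 3-correlated-factor latent trait
model behind the 44 dichotomous personality items, the night-level
actigraphy model (person-level means and night-to-night SDs that are
linear / log-linear in the latent traits and covariates), and the latent
components behind the PSQI item responses.

One global seed expands into per-stage child seeds through a fixed
derivation (``numpy.random.SeedSequence([seed, stage_code])``), so each
generation stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

#: Fixed per-stage codes for the seed derivation. Never reordered.
STAGE_CODES = {
    "subjects": 11,
    "items": 12,
    "nights": 13,
    "psqi": 14,
    "subsample": 15,
    "parallel_analysis": 21,
    "permutation": 31,
    "folds": 41,
    "jitter": 51,
    "replicates": 61,
}

#: Order of the coefficient vector applied to person-level predictors.
EFFECT_ORDER = ("core", "vitality", "ordinariness", "age_z", "sex")

#: Latent personality factors, in canonical order.
FACTORS = ("core", "vitality", "ordinariness")

#: Actigraphy parameters summarized per subject (Table-1 panel order).
SLEEP_PARAMS = (
    "sleep_onset_latency",
    "sleep_onset_time",
    "sleep_offset_time",
    "sleep_duration",
    "nwak",
    "waso",
    "sleep_efficiency",
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child RNG for one generation stage, derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), STAGE_CODES[stage]]))


def stage_seed(seed: int, stage: str) -> int:
    """Integer child seed (< 2**31) for interfaces that take a plain seed."""
    return int(np.random.SeedSequence([int(seed), STAGE_CODES[stage]]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ItemSpec:
    """One dichotomous questionnaire item of the latent probit model.

    The latent response is ``y* = a F + sqrt(1 - a^2) e`` with ``e``
    standard normal, and the item is endorsed when ``y* > threshold``.
    Under this model the implied tetrachoric correlation of two items is
    ``a_i a_j phi_ij`` where ``phi`` is the latent factor correlation.
    """

    item: str
    factor: str           # one of FACTORS
    loading: float        # a in [0, 1)
    threshold: float      # tau; endorsement rate is Phi(-tau)
    keyed_positive: bool  # direction w.r.t. the hypomanic pole (total score)


def _default_items() -> tuple[ItemSpec, ...]:
    # 18 hypomanic-core, 14 social-vitality, 12 ordinariness items,
    # interleaved in questionnaire order.  Loadings/thresholds cycle
    # through fixed values giving endorsement rates of roughly 0.14-0.38,
    # matching a low-scoring elderly population.
    spec = {
        "core": (18, [0.72, 0.66, 0.60, 0.55, 0.75, 0.63], [0.60, 0.90, 1.10, 0.75, 0.50, 1.00]),
        "vitality": (14, [0.70, 0.62, 0.57, 0.67, 0.74], [0.50, 0.80, 1.00, 0.65, 0.35]),
        "ordinariness": (12, [0.68, 0.60, 0.55, 0.72], [0.30, 0.60, 0.85, 0.45]),
    }
    per_factor: list[list[ItemSpec]] = []
    for fac, (n, loads, thrs) in spec.items():
        per_factor.append(
            [
                ItemSpec(
                    item="",
                    factor=fac,
                    loading=loads[i % len(loads)],
                    threshold=thrs[i % len(thrs)],
                    keyed_positive=fac != "ordinariness",
                )
                for i in range(n)
            ]
        )
    # interleave core/vitality/ordinariness to mimic a mixed item order
    order = []
    idx = [0, 0, 0]
    pattern = [0, 1, 0, 2, 1, 0, 2, 1, 0, 1, 2]  # repeats; 18/14/12 exhausted in turn
    k = 0
    while len(order) < 44:
        f = pattern[k % len(pattern)]
        k += 1
        if idx[f] < len(per_factor[f]):
            order.append(per_factor[f][idx[f]])
            idx[f] += 1
        else:
            continue
    return tuple(
        replace(it, item=f"q{i + 1:02d}") for i, it in enumerate(order)
    )


# ---------------------------------------------------------------------------
# default effect structure (study conditions)
# ---------------------------------------------------------------------------

def _default_level_effects() -> dict[str, list[float]]:
    # coefficients over (core, vitality, ordinariness, age_z, sex) on the
    # person-level mean (identity link for times/duration; log link for
    # latency median, NWAK rate and WASO mean).
    return {
        "sleep_onset_time": [0.0, 0.0, 2.0, -6.0, 0.0],
        "sleep_onset_latency": [0.0, 0.0, 0.0, 0.06, 0.0],
        "sleep_duration": [-3.0, -1.5, 1.0, -8.0, 6.0],
        "nwak": [0.025, 0.020, -0.005, 0.08, -0.05],
        "waso": [0.020, 0.015, -0.015, 0.10, -0.05],
    }


def _default_variability_effects() -> dict[str, list[float]]:
    # coefficients on the log of the person-level night-to-night SD
    # (for NWAK variability is governed by the Poisson rate; for latency
    # the coefficient acts on the log-scale SD of log-latency).
    return {
        "sleep_onset_time": [0.035, 0.035, 0.000, 0.000, 0.0],
        "sleep_onset_latency": [0.000, 0.020, 0.000, 0.000, 0.0],
        "sleep_duration": [0.030, 0.030, 0.000, 0.015, 0.0],
        # core coefficient fixed by Monte Carlo calibration so that the
        # population partial Spearman (core, ISD WASO | age, sex) is 0.12
        "waso": [0.046, 0.025, -0.035, 0.020, 0.0],
    }


def _default_psqi_effects() -> dict[str, list[float]]:
    # coefficients on the standardized latent PSQI components
    return {
        "latency": [0.12, -0.10, -0.12, 0.05, 0.02],
        "duration": [-0.12, 0.02, 0.10, -0.08, 0.00],
        "extra_wake": [0.10, -0.09, -0.11, 0.10, 0.00],
        "sleepiness": [0.12, 0.07, -0.11, 0.00, -0.02],
        "quality": [0.14, -0.08, -0.12, 0.05, 0.08],
        "disturbance": [0.10, -0.05, -0.08, 0.08, 0.10],
        "bedtime": [0.02, 0.03, 0.00, -0.05, 0.00],
        "medication": [0.0, 0.0, 0.0, 0.0, 0.0],
    }


def _default_noise_scales() -> dict[str, float]:
    # baselines and residual scales of the night-level model; times are
    # minutes on the linear axis referenced to 12:00 noon.
    return {
        "onset_mean": 660.0,       # 23:00
        "onset_between_sd": 42.0,
        "onset_night_sd": 28.0,
        "latency_log_median": 2.64,   # log(14 min)
        "latency_between_sd": 0.45,
        "latency_night_log_sd": 0.55,
        "latency_night_log_sd_u": 0.25,
        "duration_mean": 420.0,
        "duration_between_sd": 40.0,
        "duration_night_sd": 32.0,
        "nwak_log_rate": 0.788,       # log(2.2 awakenings/night)
        "nwak_between_sd": 0.45,
        "waso_log_mean": 3.64,        # log(38 min)
        "waso_between_sd": 0.45,
        "waso_night_sd": 20.0,
        "sigma_u_sd": 0.30,           # person-level heterogeneity of log night SD
        "ses_vitality": 0.45,         # SES loading on latent social vitality
        "ses_noise_sd": 0.893,        # keeps var(ses) == 1
        "psqi_latent_noise_sd": 1.0,
    }


def _default_factor_corr() -> list[list[float]]:
    return [
        [1.0, 0.4, -0.3],
        [0.4, 1.0, -0.2],
        [-0.3, -0.2, 1.0],
    ]


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic cohort."""

    n_subjects: int = 2861
    n_actigraphy: int = 771
    n_psqi: int = 1766
    age_range: tuple[float, float] = (60.0, 82.0)
    p_female: float = 0.479
    factor_corr: list[list[float]] = field(default_factory=_default_factor_corr)
    items: tuple[ItemSpec, ...] = field(default_factory=_default_items)
    nights_dist: dict[int, float] = field(default_factory=lambda: {5: 0.04, 6: 0.02, 7: 0.94})
    level_effects: dict[str, list[float]] = field(default_factory=_default_level_effects)
    variability_effects: dict[str, list[float]] = field(default_factory=_default_variability_effects)
    psqi_effects: dict[str, list[float]] = field(default_factory=_default_psqi_effects)
    noise_scales: dict[str, float] = field(default_factory=_default_noise_scales)
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        R = np.asarray(self.factor_corr, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise ValueError("factor_corr must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("factor_corr must be positive definite")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("factor_corr must have unit diagonal")
        p = np.array(list(self.nights_dist.values()), dtype=float)
        if not np.isclose(p.sum(), 1.0) or (p < 0).any():
            raise ValueError("nights_dist probabilities must be nonnegative and sum to 1")
        if not set(self.nights_dist) <= {5, 6, 7}:
            raise ValueError("nights_dist supports nights in {5, 6, 7}")
        if len(self.items) != 44:
            raise ValueError(f"expected 44 items, got {len(self.items)}")
        for it in self.items:
            if not (0.0 <= it.loading < 1.0):
                raise ValueError(f"item {it.item}: loading must lie in [0, 1)")
            if it.factor not in FACTORS:
                raise ValueError(f"item {it.item}: unknown factor {it.factor!r}")
        for name, d in (("level_effects", self.level_effects),
                        ("variability_effects", self.variability_effects),
                        ("psqi_effects", self.psqi_effects)):
            for k, v in d.items():
                if len(v) != len(EFFECT_ORDER):
                    raise ValueError(f"{name}[{k!r}] must have {len(EFFECT_ORDER)} coefficients")
        for k, v in self.noise_scales.items():
            if k.endswith("_sd") and v < 0:
                raise ValueError(f"noise_scales[{k!r}] must be >= 0")
        if not (0.0 <= self.p_female <= 1.0):
            raise ValueError("p_female must be a probability")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low < high")
        if not (0 < self.n_actigraphy <= self.n_subjects):
            raise ValueError("n_actigraphy must be in (0, n_subjects]")
        if not (0 < self.n_psqi <= self.n_subjects):
            raise ValueError("n_psqi must be in (0, n_subjects]")

    # ------------------------------------------------------------------
    # named study conditions
    # ------------------------------------------------------------------
    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """The effect-bearing study condition (Table-1-like effect sizes).

        Subsample sizes are clamped to the cohort size, so shrinking
        ``n_subjects`` alone yields a fully-overlapping small cohort.
        """
        cfg = cls(seed=seed, **overrides)
        cfg.n_actigraphy = min(cfg.n_actigraphy, cfg.n_subjects)
        cfg.n_psqi = min(cfg.n_psqi, cfg.n_subjects)
        cfg.validate()
        return cfg

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """All cross-domain (trait -> sleep) effects set to zero.

        Covariate (age, sex) effects on sleep are retained so covariate
        adjustment stays meaningful under the null.
        """
        cfg = cls.default(seed=seed, **overrides)
        for d in (cfg.level_effects, cfg.variability_effects, cfg.psqi_effects):
            for k in d:
                v = list(d[k])
                v[0] = v[1] = v[2] = 0.0
                d[k] = v
        cfg.validate()
        return cfg

    @classmethod
    def strong(cls, seed: int = 0, scale: float = 3.0, **overrides) -> "CohortConfig":
        """Trait -> sleep effects scaled up for qualitative direction checks."""
        cfg = cls.default(seed=seed, **overrides)
        for d in (cfg.level_effects, cfg.variability_effects, cfg.psqi_effects):
            for k in d:
                v = list(d[k])
                for i in range(3):
                    v[i] = v[i] * scale
                d[k] = v
        cfg.validate()
        return cfg

    # ------------------------------------------------------------------
    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)

    def effect_vector(self, table: str, param: str) -> np.ndarray:
        d = getattr(self, table)
        return np.asarray(d.get(param, [0.0] * len(EFFECT_ORDER)), dtype=float)

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["items"] = [asdict(it) for it in self.items]
        d["age_range"] = list(self.age_range)
        d["nights_dist"] = {int(k): float(v) for k, v in self.nights_dist.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["items"] = tuple(ItemSpec(**it) for it in d["items"])
        d["age_range"] = tuple(d["age_range"])
        d["nights_dist"] = {int(k): float(v) for k, v in d["nights_dist"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
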