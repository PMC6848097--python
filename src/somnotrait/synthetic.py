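"""Synthetic cohort generator.

Emulates the statistical structure assumed by the analysis pipeline: an
elderly population cohort (ages 60-82) in which three correlated latent
personality factors (hypomanic core, social vitality, ordinariness)
drive dichotomous questionnaire item responses through a probit
threshold model, and exert small configurable effects both on the
person-level *mean* and on the person-level *night-to-night SD* of
actigraphic sleep parameters, as well as on latent components behind
PSQI item responses.

Marginal night models: sleep-onset time and duration are normal, onset
latency lognormal, awakenings Poisson, WASO gamma -- right-skewed
non-negative marginals resembling actigraphy data.  Nightly draws are
truncated to plausible ranges by resampling (never clipping), so no
point mass accumulates at the bounds.

Latent truth columns are returned in a separate table that downstream
analysis stages never consume; they exist only for recovery tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig, EFFECT_ORDER, FACTORS
from .errors import ConfigurationError

_MAX_RESAMPLE = 100

#: plausible nightly ranges used by resampling truncation (minutes)
_RANGES = {
    "sleep_duration": (120.0, 720.0),
    "sleep_onset_latency": (0.0, 300.0),
    "waso": (0.0, 400.0),
}


def _clock(minutes_after_noon: np.ndarray) -> np.ndarray:
    """Format minutes-after-12:00 as HH:MM 24 h clock strings."""
    m = (np.round(minutes_after_noon).astype(int) + 720) % 1440
    return np.char.add(
        np.char.add(np.char.zfill((m // 60).astype(str), 2), ":"),
        np.char.zfill((m % 60).astype(str), 2),
    )


def _design(subjects: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """Person-level predictor matrix in EFFECT_ORDER (traits, age_z, sex)."""
    lo, hi = config.age_range
    age_z = (subjects["age"].to_numpy() - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))
    return np.column_stack(
        [
            subjects["latent_core"].to_numpy(),
            subjects["latent_vitality"].to_numpy(),
            subjects["latent_ordinariness"].to_numpy(),
            age_z,
            subjects["sex"].to_numpy().astype(float),
        ]
    )


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

def generate_subjects(config: CohortConfig) -> pd.DataFrame:
    """Generate the subject table, including latent trait truth columns.

    Latent traits are drawn from the configured trivariate correlation
    structure; the socioeconomic index loads on latent social vitality
    (so that covariates explain trait variance, as in population data).
    Membership indicators for the actigraphy and PSQI subsamples are
    drawn without replacement.
    """
    config.validate()
    rng = config.rng("subjects")
    n = config.n_subjects

    R = np.asarray(config.factor_corr, dtype=float)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - validate() catches first
        raise ConfigurationError("factor_corr is not positive definite") from exc
    latent = rng.standard_normal((n, 3)) @ L.T

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    sex = (rng.random(n) < config.p_female).astype(int)
    ns = config.noise_scales
    ses = ns["ses_vitality"] * latent[:, 1] + rng.normal(0.0, ns["ses_noise_sd"], size=n)
    bmi = 27.5 + 0.5 * (age - (lo + hi) / 2) / ((hi - lo) / np.sqrt(12)) + rng.normal(0, 4.0, size=n)

    sub_rng = config.rng("subsample")
    has_act = np.zeros(n, dtype=bool)
    has_act[sub_rng.choice(n, size=config.n_actigraphy, replace=False)] = True
    has_psqi = np.zeros(n, dtype=bool)
    has_psqi[sub_rng.choice(n, size=config.n_psqi, replace=False)] = True

    width = len(str(n))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:0{width}d}" for i in range(n)],
            "age": np.round(age, 2),
            "sex": sex,
            "ses": np.round(ses, 4),
            "bmi": np.round(bmi, 2),
            "has_actigraphy": has_act.astype(int),
            "has_psqi": has_psqi.astype(int),
            "latent_core": latent[:, 0],
            "latent_vitality": latent[:, 1],
            "latent_ordinariness": latent[:, 2],
        }
    )


def split_truth(subjects: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into the analysis-visible table and the latent truth table."""
    truth_cols = ["latent_core", "latent_vitality", "latent_ordinariness"]
    truth = subjects[["subject_id"] + truth_cols].copy()
    visible = subjects.drop(columns=truth_cols)
    return visible, truth


# ---------------------------------------------------------------------------
# questionnaire items
# ---------------------------------------------------------------------------

def generate_item_responses(subjects: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Binary item matrix from the latent probit threshold model.

    Item ``j`` on factor ``F`` with loading ``a`` and threshold ``tau``
    is endorsed when ``a F + sqrt(1 - a^2) e > tau``; the implied
    tetrachoric correlation between items i, j is ``a_i a_j phi_ij``.
    """
    config.validate()
    rng = config.rng("items")
    n = len(subjects)
    fidx = {f: i for i, f in enumerate(FACTORS)}
    latent = subjects[["latent_core", "latent_vitality", "latent_ordinariness"]].to_numpy()

    out = {"subject_id": subjects["subject_id"].to_numpy()}
    for it in config.items:
        a = it.loading
        ystar = a * latent[:, fidx[it.factor]] + np.sqrt(1.0 - a * a) * rng.standard_normal(n)
        out[it.item] = (ystar > it.threshold).astype(int)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# actigraphy nights
# ---------------------------------------------------------------------------

def generate_nights(subjects: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Night-level actigraphy records for the actigraphy subsample.

    Per subject, each parameter's person-level mean is linear (identity
    link; log link for latency median, awakening rate and WASO mean) and
    its person-level night SD log-linear in (core, vitality,
    ordinariness, age_z, sex).  Sleep-offset time is derived as onset +
    duration + WASO, so the stored fields are internally consistent with
    time in bed = latency + duration + WASO (bedtime to get-up time).
    """
    config.validate()
    rng = config.rng("nights")
    ns = config.noise_scales

    sub = subjects[subjects["has_actigraphy"] == 1].reset_index(drop=True)
    n = len(sub)
    X = _design(sub, config)

    def lvl(p):
        return X @ config.effect_vector("level_effects", p)

    def var(p):
        return X @ config.effect_vector("variability_effects", p)

    u = lambda: rng.normal(0.0, ns["sigma_u_sd"], size=n)

    def person_means():
        onset_mu = ns["onset_mean"] + lvl("sleep_onset_time") + rng.normal(0, ns["onset_between_sd"], n)
        lat_m = ns["latency_log_median"] + lvl("sleep_onset_latency") + rng.normal(0, ns["latency_between_sd"], n)
        dur_mu = ns["duration_mean"] + lvl("sleep_duration") + rng.normal(0, ns["duration_between_sd"], n)
        waso_mu = np.exp(ns["waso_log_mean"] + lvl("waso") + rng.normal(0, ns["waso_between_sd"], n))
        return onset_mu, lat_m, dur_mu, waso_mu

    # person-level plausibility: leave headroom for nightly variation so
    # every person can produce valid nights (bedtime after noon, get-up
    # before next noon)
    def person_bad(onset_mu, lat_m, dur_mu, waso_mu):
        return (
            (onset_mu < 500.0) | (onset_mu > 860.0)
            | (dur_mu < 240.0) | (dur_mu > 600.0)
            | (lat_m > np.log(180.0))
            | (waso_mu > 150.0)
            | (onset_mu + dur_mu + waso_mu > 1300.0)
        )

    onset_mu, lat_m, dur_mu, waso_mu = person_means()
    bad = person_bad(onset_mu, lat_m, dur_mu, waso_mu)
    for _ in range(_MAX_RESAMPLE):
        if not bad.any():
            break
        o2, l2, d2, w2 = person_means()
        onset_mu = np.where(bad, o2, onset_mu)
        lat_m = np.where(bad, l2, lat_m)
        dur_mu = np.where(bad, d2, dur_mu)
        waso_mu = np.where(bad, w2, waso_mu)
        bad = person_bad(onset_mu, lat_m, dur_mu, waso_mu)
    else:
        raise ConfigurationError(
            "person-level resampling failed; configured effect sizes or "
            "baselines are implausible"
        )

    onset_sd = ns["onset_night_sd"] * np.exp(var("sleep_onset_time") + u())
    lat_s = ns["latency_night_log_sd"] * np.exp(
        var("sleep_onset_latency") + rng.normal(0.0, ns["latency_night_log_sd_u"], size=n)
    )
    dur_sd = ns["duration_night_sd"] * np.exp(var("sleep_duration") + u())
    nwak_rate = np.exp(ns["nwak_log_rate"] + lvl("nwak") + rng.normal(0, ns["nwak_between_sd"], n))
    waso_sd = ns["waso_night_sd"] * np.exp(var("waso") + u())

    probs = np.array([config.nights_dist.get(k, 0.0) for k in (5, 6, 7)])
    n_nights = rng.choice([5, 6, 7], size=n, p=probs)

    rep = np.repeat(np.arange(n), n_nights)
    m = len(rep)
    night_index = np.concatenate([np.arange(1, k + 1) for k in n_nights])

    shape = (waso_mu / waso_sd) ** 2
    scale = waso_sd**2 / waso_mu

    def draw_all():
        return (
            rng.normal(onset_mu[rep], onset_sd[rep]),
            np.exp(rng.normal(lat_m[rep], lat_s[rep])),
            rng.normal(dur_mu[rep], dur_sd[rep]),
            rng.gamma(shape[rep], scale[rep], size=m),
        )

    def violates(onset, latency, duration, waso):
        # marginal plausibility plus structural night constraints: bedtime
        # (onset - latency) after the noon reference and get-up
        # (onset + duration + WASO) before the next noon, so linearized
        # clock times never wrap
        lat_lo, lat_hi = _RANGES["sleep_onset_latency"]
        dur_lo, dur_hi = _RANGES["sleep_duration"]
        waso_lo, waso_hi = _RANGES["waso"]
        return (
            (latency <= lat_lo) | (latency >= lat_hi)
            | (duration <= dur_lo) | (duration >= dur_hi)
            | (waso < waso_lo) | (waso >= waso_hi)
            | (onset - latency <= 0)
            | (onset + duration + waso >= 1410.0)
        )

    onset, latency, duration, waso = draw_all()
    bad = violates(onset, latency, duration, waso)
    for _ in range(_MAX_RESAMPLE):
        if not bad.any():
            break
        o2, l2, d2, w2 = draw_all()
        onset = np.where(bad, o2, onset)
        latency = np.where(bad, l2, latency)
        duration = np.where(bad, d2, duration)
        waso = np.where(bad, w2, waso)
        bad = violates(onset, latency, duration, waso)
    else:
        raise ConfigurationError(
            f"night resampling failed after {_MAX_RESAMPLE} rounds; "
            "configured distributions are implausible for a single night"
        )
    nwak = rng.poisson(nwak_rate[rep])
    offset = onset + duration + waso

    return pd.DataFrame(
        {
            "subject_id": sub["subject_id"].to_numpy()[rep],
            "night_index": night_index,
            "sleep_onset_time": _clock(onset),
            "sleep_offset_time": _clock(offset),
            "sleep_onset_latency": np.round(latency, 2),
            "nwak": nwak,
            "waso": np.round(waso, 2),
            "sleep_duration": np.round(duration, 2),
        }
    )


def true_night_sds(subjects: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Population (noise-free) person-level night SDs implied by the config.

    Returns the *systematic* part of each person's log night SD, i.e.
    without the person-level heterogeneity draw; used by oracle tests.
    """
    sub = subjects[subjects["has_actigraphy"] == 1].reset_index(drop=True)
    X = _design(sub, config)
    ns = config.noise_scales
    out = {"subject_id": sub["subject_id"].to_numpy()}
    base = {
        "sleep_onset_time": ns["onset_night_sd"],
        "sleep_duration": ns["duration_night_sd"],
        "waso": ns["waso_night_sd"],
        "sleep_onset_latency": ns["latency_night_log_sd"],
    }
    for p, b in base.items():
        out[f"sigma_{p}"] = b * np.exp(X @ config.effect_vector("variability_effects", p))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# PSQI items
# ---------------------------------------------------------------------------

def _cut(x: np.ndarray, thresholds) -> np.ndarray:
    """Ordinal 0..len(thresholds) via increasing thresholds."""
    return np.searchsorted(np.asarray(thresholds, dtype=float), x, side="left").astype(int)


def generate_psqi(subjects: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """PSQI item responses for the PSQI subsample.

    Standardized latent components (latency, duration, extra wake,
    quality, disturbance, sleepiness, bedtime, medication) are linear in
    the traits and covariates plus unit-variance noise, then mapped
    monotonically to the item scales: reported minutes and hours, clock
    times, and 0-3 ordinal frequency ratings.
    """
    config.validate()
    rng = config.rng("psqi")
    ns = config.noise_scales

    sub = subjects[subjects["has_psqi"] == 1].reset_index(drop=True)
    n = len(sub)
    X = _design(sub, config)

    comps = ("latency", "duration", "extra_wake", "quality", "disturbance",
             "sleepiness", "bedtime", "medication")
    signal = {c: X @ config.effect_vector("psqi_effects", c) for c in comps}

    def draw_noise():
        return {c: rng.normal(0.0, ns["psqi_latent_noise_sd"], size=n) for c in comps}

    def derive(L):
        duration_h = np.clip(np.round((7.1 + 0.9 * L["duration"]) * 4) / 4.0, 3.0, 11.0)
        bedtime_min = 630.0 + 45.0 * L["bedtime"]            # ~22:30 after noon
        extra_wake = np.clip(np.exp(np.log(45.0) + 0.6 * L["extra_wake"]), 5.0, 240.0)
        getup_min = bedtime_min + duration_h * 60.0 + extra_wake
        return duration_h, bedtime_min, extra_wake, getup_min

    noise = draw_noise()
    L = {c: signal[c] + noise[c] for c in comps}
    duration_h, bedtime_min, extra_wake, getup_min = derive(L)
    # reported bedtime must fall after noon and get-up before the next
    # noon, else linearized clock times wrap; resample the offending
    # subjects' latent noise (never clip: no point mass at the boundary)
    bad = (bedtime_min < 480.0) | (getup_min >= 1410.0)
    for _ in range(_MAX_RESAMPLE):
        if not bad.any():
            break
        fresh = draw_noise()
        for c in comps:
            noise[c] = np.where(bad, fresh[c], noise[c])
        L = {c: signal[c] + noise[c] for c in comps}
        duration_h, bedtime_min, extra_wake, getup_min = derive(L)
        bad = (bedtime_min < 480.0) | (getup_min >= 1410.0)
    else:
        raise ConfigurationError(
            "PSQI resampling failed; configured effects are implausible"
        )

    L_lat = L["latency"]
    L_qual = L["quality"]
    L_dist = L["disturbance"]
    L_sleepy = L["sleepiness"]
    L_med = L["medication"]

    latency_min = np.clip(np.round(np.exp(np.log(18.0) + 0.8 * L_lat)), 1, 180).astype(int)

    out = {
        "subject_id": sub["subject_id"].to_numpy(),
        "bedtime": _clock(bedtime_min),
        "latency_min": latency_min,
        "getup_time": _clock(getup_min),
        "duration_h": duration_h,
        "freq_latency": _cut(0.8 * L_lat + 0.6 * rng.standard_normal(n), [0.5, 1.2, 2.0]),
        "quality": _cut(L_qual, [0.6, 1.7, 2.6]),
    }
    for j in range(1, 10):
        out[f"disturb_{j}"] = _cut(
            0.7 * L_dist + 0.71 * rng.standard_normal(n), [0.0, 1.6, 2.6]
        )
    out["medication"] = _cut(L_med, [1.3, 1.8, 2.3])
    out["sleepiness"] = _cut(L_sleepy, [0.5, 1.5, 2.4])
    out["enthusiasm"] = _cut(0.6 * L_sleepy + 0.8 * rng.standard_normal(n), [0.8, 1.7, 2.5])
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# one-call cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> dict[str, pd.DataFrame]:
    """Generate all cohort tables; the truth table is kept separate."""
    subjects_full = generate_subjects(config)
    items = generate_item_responses(subjects_full, config)
    nights = generate_nights(subjects_full, config)
    psqi = generate_psqi(subjects_full, config)
    subjects, truth = split_truth(subjects_full)
    return {
        "subjects": subjects,
        "truth": truth,
        "hps_items": items,
        "nights": nights,
        "psqi_items": psqi,
    }
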