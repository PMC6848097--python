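import numpy as np
import pandas as pd
import pytest

from somnotrait import CohortConfig, analyze_cohort, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A small effect-bearing cohort with full subsample overlap."""
    return CohortConfig.default(seed=0, n_subjects=400, n_actigraphy=400, n_psqi=400)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_config, small_cohort):
    """Scores, sleep panel and covariates for the small cohort."""
    return analyze_cohort(small_cohort, small_config, k_factors=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_nights(rng, subject_id="S1", n_nights=6):
    """A plausible random nights table for one subject."""
    onset = rng.uniform(600, 750, n_nights)
    duration = rng.uniform(360, 480, n_nights)
    waso = rng.uniform(5, 80, n_nights)
    clock = lambda m: [f"{(int(round(x)) + 720) % 1440 // 60:02d}:{(int(round(x)) + 720) % 1440 % 60:02d}" for x in m]
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "night_index": np.arange(1, n_nights + 1),
            "sleep_onset_time": clock(onset),
            "sleep_offset_time": clock(onset + duration + waso),
            "sleep_onset_latency": rng.uniform(2, 60, n_nights).round(2),
            "nwak": rng.integers(0, 6, n_nights),
            "waso": waso.round(2),
            "sleep_duration": duration.round(2),
        }
    )
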