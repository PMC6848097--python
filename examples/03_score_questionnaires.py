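"""Score the HPS (total + subscale sums) and the PSQI (components + total).

The HPS total counts hypomanic-pole responses over all 44 items
(reverse-keyed ordinariness items count non-endorsement); PSQI items
are banded into seven 0-3 components summed to a 0-21 total, higher
meaning worse sleep.
"""

from somnotrait import (
    CohortConfig, ScoringKey, generate_cohort,
    score_hps_subscales_sum, score_hps_total, score_psqi,
)

cfg = CohortConfig.default(seed=42, n_subjects=800)
tables = generate_cohort(cfg)
key = ScoringKey.from_config(cfg)

total = score_hps_total(tables["hps_items"], key)
subs = score_hps_subscales_sum(tables["hps_items"], key)
print(f"HPS total: mean {total['hps_total'].mean():.1f} "
      f"(SD {total['hps_total'].std():.1f}) of a 0-44 range")
print(subs.drop(columns='subject_id').mean().round(1).to_string())

psqi = score_psqi(tables["psqi_items"])
print(f"\nPSQI total: mean {psqi['psqi_total'].mean():.1f} "
      f"(SD {psqi['psqi_total'].std():.1f}) of a 0-21 range")
print("components:", psqi[[f"psqi_c{i}" for i in range(1, 8)]].mean().round(2).tolist())
# Low PSQI totals are expected here: the emulated cohort excludes
# subjects with sleep-disrupting disease or medication.
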