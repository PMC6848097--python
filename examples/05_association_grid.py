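"""The core analysis: 84 covariate-adjusted rank correlations.

Each of the 4 personality scores (HPS total + 3 subscales) is
correlated with each of the 21 sleep variables (7 actigraphy means,
7 actigraphy ISDs, 7 PSQI variables) by partial Spearman correlation
adjusting for age and sex, with joint Benjamini-Hochberg correction.
"""

from somnotrait import (
    SCORE_COLUMNS, SLEEP_PANEL, CohortConfig, adjust_pvalues,
    analyze_cohort, correlate_grid, generate_cohort,
)

cfg = CohortConfig.default(seed=42)   # 2861 / 771 / 1766 cohort
analysis = analyze_cohort(generate_cohort(cfg), cfg, k_factors=3)
grid = adjust_pvalues(
    correlate_grid(analysis.scores, analysis.sleep, analysis.covariates,
                   score_cols=list(SCORE_COLUMNS), sleep_cols=list(SLEEP_PANEL)),
    method="bh",
)

print(f"{len(grid)} association records; "
      f"{(grid['p'] < 0.05).sum()} significant at p < .05, "
      f"{(grid['p_adj'] < 0.05).sum()} after BH correction")
print("\nstrongest associations:")
top = grid.reindex(grid["rho"].abs().sort_values(ascending=False).index).head(6)
print(top[["personality_score", "sleep_variable", "rho", "p", "n"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3g}"))
# Night-to-night variability (ISD) variables dominate the top of the
# list: the trait is linked more to sleep *irregularity* than to mean
# sleep levels, and ordinariness correlates in the opposite direction.
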