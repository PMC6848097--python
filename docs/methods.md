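# Methods

## Scope and model overview

The package implements the full analysis chain linking a dimensional
hypomanic-personality trait to sleep, exercised on synthetic cohorts
whose statistical structure matches the study conditions: an elderly
(60–82 y) population sample of which 2861 subjects have complete
44-item HPS responses, 771 have 5–7 nights of actigraphy (mean 6.9),
and 1766 have PSQI data. Because the analysis consumes actigraphy at
the per-night parameter level, no raw accelerometry is simulated, and
the clinical exclusion cascade is modeled only as pre-filtered input.

## Synthetic cohort generator

### Latent traits and items

Subjects carry three standardized latent factors — hypomanic core,
social vitality, ordinariness — drawn from a configurable correlation
matrix (defaults 0.40 core–vitality, −0.30 core–ordinariness, −0.20
vitality–ordinariness). Each of the 44 dichotomous items belongs to
exactly one factor with loading `a ∈ [0, 1)` and threshold `τ` under
the standard factor-analytic probit model: the latent response is
`y* = a·F + √(1−a²)·ε`, the item is endorsed when `y* > τ`. Two items
then have implied tetrachoric correlation `aᵢaⱼφᵢⱼ` — a closed form
used as the analytic oracle for the factor-analysis tests. Default
loadings cycle through 0.55–0.75 and thresholds through 0.30–1.10
(endorsement rates ≈ 0.14–0.38), giving keyed totals with mean ≈ 16 of
44. The socioeconomic index loads 0.45 on latent vitality so that
covariates explain real trait variance; BMI is a pure nuisance
covariate.

### Nights

Per sleep parameter, the person-level mean is linear (identity link for
onset time and duration; log link for latency median, awakening rate,
WASO mean) and the person-level night SD log-linear in (core, vitality,
ordinariness, standardized age, sex), each with person-level residual
heterogeneity (SD 0.30 on the log-SD scale). Nightly draws use
right-skewed non-negative marginals resembling actigraphy data: onset
time and duration normal, latency lognormal, NWAK Poisson (so its
night-to-night variability follows its rate), WASO gamma with the
person's mean and SD. Baselines are typical for healthy elderly
sleepers: onset 23:00, duration 420 min, latency median 14 min, WASO
mean 38 min, 2.2 awakenings/night. Offset time is derived as onset +
duration + WASO, so all stored fields are internally consistent with
time in bed = latency + duration + WASO.

Implausible draws are rejected by **resampling, never clipping** (no
point masses at bounds; at most 100 rounds, then a configuration
error). Constraints act at two levels: person-level parameter vectors
must leave headroom for valid nights (onset mean 500–860 min after
noon, duration mean 240–600 min, WASO mean ≤ 150 min, latency median ≤
180 min, onset+duration+WASO ≤ 1300), and each night must satisfy
bedtime after noon and get-up before the next noon (onset − latency > 0,
onset + duration + WASO < 1410 min) plus marginal ranges (duration
120–720, latency 0–300, WASO 0–400 min). Without the get-up constraint
a rare long night wraps the 24-h clock and produces a catastrophic
offset-time ISD outlier.

Default trait→sleep coefficients were chosen once to give population
partial correlations of |ρ| ≈ 0.05–0.15, the magnitude regime of the
study; the core coefficient on log σ(WASO) is 0.046, fixed by a
multi-seed n = 150,000 Monte Carlo so the population partial Spearman
between latent core and measured ISD(WASO), adjusting for age and sex,
is 0.120. This value is the reference for the effect-recovery checks.
`CohortConfig.null()` zeroes all trait coefficients (keeping covariate
effects, so adjustment stays meaningful under the null);
`CohortConfig.strong()` scales them up for qualitative direction
checks.

### PSQI

Eight standardized latent components (latency, duration, extra wake,
quality, disturbance, sleepiness, bedtime, medication) are linear in
traits and covariates plus unit normal noise, then mapped monotonically
to item scales: reported latency `exp(log 18 + 0.8·L)` minutes, duration
`7.1 + 0.9·L` hours reported in quarter hours, bedtime 22:30 ± 45·L
min, get-up = bedtime + duration + extra wake (so reported efficiency
is internally consistent), and 0–3 ordinal ratings by fixed thresholds.
Default effect signs reproduce the study's qualitative pattern: core →
worse subjective sleep throughout; vitality → shorter reported latency
and better efficiency but *more* sleepiness; ordinariness → better
subjective sleep on all components.

### Seeds and determinism

One global seed expands to per-stage child seeds through
`SeedSequence([seed, stage_code])` with fixed stage codes, so each
stage (subjects, items, nights, PSQI, subsampling, parallel analysis,
permutation, folds, jitter) is individually reproducible. Identical
config and seed give byte-identical CSV output (fixed float format).

### What the generator does not emulate

Latent truth columns live in a separate table never read by analysis
stages. The generator omits features of real cohort data — item-level
missingness patterns, non-probit item response shapes, weekday/weekend
structure and first-night effects, device-specific scoring bias,
informative subsample selection (subsamples are drawn at random), and
any sleep-disorder tail (apnea, PLMD). Passing tests therefore
establish correctness and calibration of the *statistical machinery*
under the assumed generative model, not fidelity of any particular
effect estimate to a real population.

## Statistical procedures and numerical choices

**ISD** is the sample SD (n−1 denominator) across a subject's nights;
subjects need ≥ 5 nights (configurable), otherwise they are dropped
with a log entry, never imputed. Onset/offset clock times are
linearized as minutes from a 12:00 reference before any statistic —
a linear, not circular, treatment, adequate for a population whose
sleep is anchored to night and documented as a limitation for
free-running rhythms. Efficiency is computed per night and then
aggregated (not as a ratio of means), keeping the mean and ISD
definitions symmetric.

**Tetrachoric correlations** fix thresholds at the sample margins via
the inverse normal; the remaining one-parameter MLE is the root of
Φ₂(τ₁, τ₂, ρ) = p̂₀₀ (at that root all four cell probabilities equal
their sample frequencies, hence it maximizes the multinomial
likelihood). Φ₂ is evaluated through Owen's T, and the matrix version
solves all pairs by 64-step vectorized bisection on ρ ∈ ±(1−10⁻⁶) —
fast enough to build a 44 × 44 matrix in milliseconds, which makes the
parallel-analysis null below affordable. A zero cell triggers a
continuity correction (+0.5 to all cells), flagged in the result;
|ρ| is capped at 1−10⁻⁶.

**PSD smoothing** clips eigenvalues at 10⁻⁶ and rescales to unit
diagonal; an already-PSD matrix passes through unchanged.

**Retention** uses Horn's parallel analysis with 100 simulated null
datasets and the 95th-percentile rule, counting *leading consecutive*
eigenvalues above the reference. For a tetrachoric input the null
datasets are dichotomized independent normals at the observed item
margins, analyzed with the same tetrachoric estimator and smoothing, so
observed and reference eigenvalues share the estimator's sampling
noise; plain correlation matrices use Gaussian/Pearson nulls.

**Extraction** is iterated principal-axis factoring from squared
multiple correlations (tolerance 10⁻⁶ on communalities, max 1000
iterations, error with trace on non-convergence; Heywood communalities
clipped to 1 and logged). **Rotation** is promax: Kaiser-normalized
varimax followed by a least-squares transform toward the element-wise
power-4 target, factor correlations from the normalized transform;
column signs are fixed so each factor's largest-|loading| item is
positive and columns are ordered by sum of squared loadings.
**Factor scores** are Thurstone regression scores, `Z R⁻¹ (ΛΦ)` on the
standardized item matrix, standardized per column; factors are labeled
by marker-item lists (highest mean structure loading, one-to-one
assignment), falling back to explained-variance order.

**Partial Spearman** ranks x, y and each covariate (average ranks),
residualizes ranked x and y on the ranked covariates plus intercept by
least squares, and correlates the residuals; p from
`t = ρ√((n−2−k)/(1−ρ²))` with n−2−k df. Constant covariates are
dropped with a log entry; a constant x or y is an error. Each grid pair
uses its own complete cases (actigraphy and PSQI subsamples differ),
and the default correction is Benjamini–Hochberg across all 84 tests as
one family (Holm and Bonferroni are config switches). Dependent
correlations are compared with Steiger's Z (average-r covariance term).
Decile extreme groups take the ⌈0.1n⌉ lowest/highest scores extended by
boundary ties (nearest-rank rule), contrasted by tie-corrected
Kruskal–Wallis tests (all-identical values return H = 0, p = 1 by
convention).

**Permutation null.** The sleep block is shuffled rather than the
personality block, keeping covariate–personality alignment intact so
covariate adjustment remains meaningful under the null; under the null
the shuffled sleep block is consequently also de-associated from the
covariates. Per-pair complete-case masks are frozen before permuting:
sleep columns sharing a missingness pattern form a block shuffled
within its complete rows, so per-test n is constant across replicates
and within-block rank correlations are preserved exactly. The engine
pre-ranks all blocks, builds one orthonormal covariate basis per block,
and needs only a projection and a cross-product per replicate, so 10⁴
replicates take seconds and the envelope default (10⁴; 2 × 10³ in the
pipeline driver) can be raised to 10⁶ where wanted. Envelope
percentiles use the linear-interpolation rule. Fewer than 100
replicates trigger an instability warning.

**Cross-validated prediction** uses OLS (configurable learner was
considered out of scope), seeded balanced k-fold assignment,
standardization computed on each training fold only, and pooled
held-out predictions scored as 1 − SSE/SST with SST about the
full-sample mean — more stable than averaging per-fold R² with small
folds. Rank-deficient designs fall back to the minimum-norm fit (the
predictions, hence R², are unaffected by duplicated predictors) with a
log entry.

## Problem sizes used by the test and acceptance runs

Structure checks run on cohorts of 300–1200 subjects with full
subsample overlap; calibration studies use 200 null cohorts of n = 771
(type-I rate of the 84-test grid), 30 of them with 1000-replicate
envelopes (coverage), 100 effect-bearing cohorts of n = 5000 (recovery
of the configured 0.12), 25 seeded cohorts of n = 2861 (factor-count
recovery), and 10⁴-replicate permutation runs for the order-statistic
closed form 1 − r/85. Monte Carlo assertions state their tolerance
against the binomial or order-statistic sampling bounds they test.

## Known limitations

- Linear (not circular) clock-time statistics; inappropriate for
  free-running or shift-work rhythms.
- The t approximation for rank correlations is mildly conservative for
  heavily tied ordinal variables (4-level items reject at ≈ 0.047 at
  nominal 0.05 in our calibration runs); acceptable at these panel
  mixes, but exact permutation p values would be preferable for purely
  ordinal panels.
- Tetrachoric estimation assumes an underlying bivariate normal; the
  generator satisfies this by construction, real items need not.
- The PSQI generator produces internally consistent reports (efficiency
  derivable from bedtime/get-up/duration); real self-reports are often
  inconsistent, and the scorer's exclusion policy is only exercised by
  synthetic missingness in tests.
- Sum-score subscale assignment is fixed by the generating key; on real
  data it should be re-derived from the rotated loadings once and
  frozen.
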