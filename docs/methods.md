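# Methods

`wearpipe` turns raw, event-timestamped consumer-wearable streams (heart
rate, step counts, categorical sleep stages) into de-identified,
minute-harmonized series, per-day physiological features, per-user summary
features, and a cross-validated phenotype classification — driven end to
end by a synthetic cohort generator so the whole chain is testable without
any real participant data.

## Pipeline model

1. **De-identification.** Every timestamp of a user is advanced by one
   fixed offset drawn uniformly per user from a future window (default
   1–10 years, quantized to whole days). Addition of a per-user constant
   preserves all within-user time differences exactly while destroying
   absolute dates and cross-user alignment. Whole-day quantization keeps
   clock-of-day structure (sleep at night) intact, which the daily
   features depend on. Numeric values optionally receive slight zero-mean
   Gaussian noise (default sd 0.5 bpm for heart rate, 0 for steps; sleep
   categories are never perturbed); step counts are re-clamped to
   non-negative integers. The user→offset map is identifying material and
   is always written to a separate location.

2. **Harmonization.** Per individual: the 8 sleep-stage tokens are
   binarized ({asleep, light, deep, restless, REM} → 1, {awake, wake} → 0,
   unknown → missing; the mapping is a configurable dictionary), all
   streams are aggregated to a 1-minute grid (heart rate: within-minute
   mean; steps: within-minute sum; sleep: 1 if any within-minute sample is
   asleep, else 0 if any is awake, else missing), heart-rate values
   strictly below 20 bpm are removed as sensor artifacts (20 itself is
   kept), and the series are smoothed with a trailing 5-minute rolling
   mean (heart rate, steps) or rolling max (sleep). Windows are trailing
   (causal) with partial windows at the series start; a window statistic
   uses only the non-missing points and is missing only when the whole
   window is. No imputation is applied anywhere: gaps stay gaps and all
   downstream statistics are available-case.

3. **Daily features.** Days are cut at local midnight (per-user timezone,
   default UTC) into 1440-slot grids. Twelve features per user-day:
   mean heart rate, total steps, sleep hours, mean sleeping heart rate
   (minutes with sleep indicator 1), mean resting heart rate (minutes with
   step count 0 — sleep minutes included, per the literal definition; an
   awake-only variant is a flag), mean active heart rate (positive step
   count), the active-minus-sleeping difference, and five outlier
   percentages (overall HR, the three strata, steps), where an outlier
   lies more than 2 sample (n−1) standard deviations from the mean of that
   day's distribution of the variable (a per-user whole-record variant of
   the reference distribution would be a one-line change; per-day is the
   default because the features are defined per day). A zero or undefined
   standard deviation gives 0%. Empty strata yield missing features.

4. **User summaries and cohort filters.** Users without a label and users
   with fewer than 14 processed days are excluded; the rest are truncated
   to their first 90 calendar days. Seven statistics (mean, sample sd,
   min, max, 25/50/75% quartiles with linear interpolation) of each daily
   feature over a user's available days give 7 × 12 = 84 features.

5. **Classification.** Repeated k-fold (default 10 × 5) evaluation of an
   elastic-net logistic regression. Per repeat, users are split uniformly
   at random into 5 folds (sizes differ by ≤ 1; splits are not
   class-stratified by default, with a stratified flag). Per fold, a
   Yeo–Johnson power transform with subsequent centering/scaling, a
   train-median imputation of any wholly missing user-level cells, and the
   logistic model (mixing ratio 0.5, inverse regularization strength
   C = 1.0) are fitted on the four training partitions only and applied to
   the held-out partition. All out-of-fold scores of a repeat are pooled
   into one AUROC (Mann–Whitney rank form, ties half-credited) and one
   average precision (step sum over descending distinct thresholds). The
   master seed drives each repeat's split through a per-repeat derived
   seed, so results are exactly reproducible.

6. **Embedding.** For visualization, user-days with zero total steps are
   dropped, features are transformed by the signed log1p
   (sign(x)·log(1+|x|), defined on all reals because the difference
   feature can be negative and counts can be zero, and order-preserving),
   standardized per column, and projected to 2-D by a pluggable
   neighbor-embedding backend (UMAP by default, fixed seed; the backend's
   internals are treated as third-party methodology, not reimplemented).
   Per-user coordinate-wise medians summarize individuals.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `hr_floor` | 20 | bpm | heart-rate artifact threshold (strictly below removed) |
| `smooth_window` | 5 | min | trailing rolling window (mean / max) |
| `outlier_k` | 2 | SD | outlier cut-off in daily features |
| `min_days` | 14 | days | minimum processed days per user |
| `horizon_days` | 90 | days | analysis restricted to first N calendar days |
| `cv_folds` / `cv_repeats` | 5 / 10 | — | cross-validation layout |
| `l1_ratio` | 0.5 | — | elastic-net mixing (1 = lasso) |
| `regularization_strength` | 1.0 | — | inverse strength C of the logistic model |
| `rng_seed` | 0 | — | master seed for every stochastic step |

`regularization_strength` is the one modelling constant with no canonical
value; C = 1.0 (the scikit-learn convention's default) is used and the
flag is exposed everywhere so sensitivity can be probed directly (the
recovery signal sits in a handful of resting-heart-rate summary columns,
which mixed L1/L2 penalties of any moderate strength retain).

## Synthetic cohort generator

Each user gets an RNG derived from `(seed, user index)`, so cohorts are
extensible without reshuffling existing users. Heart rate is a
piecewise-constant three-level profile (sleeping < resting < active;
population draws around 55/67/97 bpm) plus white Gaussian noise (sd ≈ 3
bpm) — deliberately the simplest structure that exercises the
stratification features; there is no autocorrelation, no heart-rate
variability, and no accelerometry. One nightly sleep bout (onset ≈ 23:00,
offset ≈ 07:00, per-user and per-day jitter) emits stage tokens sampled
from the asleep-like set inside the bout and awake-like outside, with a
1% unknown rate. Steps concentrate in 2–4 daytime bouts of 20–40 minutes
scaled to a per-user daily total (≈ 8,000); positive counts occur only
while awake, zero counts are recorded all day so the resting stratum is
populated. Each stream emits one sample per minute with a random second
offset (second-precision timestamps, exercising minute aggregation);
wear gaps are simulated by dropping whole (user, stream, minute) groups
independently at a configurable rate.

Phenotype effects are level shifts: `rest_hr_delta` raises the awake
resting level of phenotype-positive users, `step_delta` and `sleep_delta`
shift daily totals and sleep duration. Because effects are pure level
shifts on independent noise, passing recovery tests shows the chain
propagates group differences through harmonization, stratification,
summarization and cross-validation without leakage or attenuation — it
does not show robustness to autocorrelated physiology, device-specific
artifacts, diurnal effect modulation, or informative missingness, none of
which the generator emulates.

## Numerical choices

- Sample (n−1) standard deviations and linear-interpolation quartiles
  throughout.
- saga solver, tol 1e-6, max_iter 2000, fixed `random_state`: on strongly
  separable synthetic cohorts the solver is stopped by the iteration cap
  rather than the tolerance; determinism is unaffected because the data,
  seed and cap fix the iterate sequence exactly.
- The penalty convention follows scikit-learn (penalty fixed relative to
  the summed loss), so uniformly duplicating every row equals doubling C;
  the test suite pins this algebraic identity.
- Constant feature columns cannot be power-transformed and pass through
  unchanged, flagged; constant columns in the embedding stage standardize
  to zero.
- Ties in AUROC receive half credit; average precision uses one threshold
  per distinct score.
- Degenerate inputs: users with zero events are skipped with a warning;
  days with no data in any stream are dropped; empty strata produce
  missing features, excluded by available-case summaries; a cohort that
  filters to nothing is a fatal error.
- Problem sizes in the test suite and acceptance script: the recovery
  study uses 30 users × 60 days (≈ 7.8 M events), the de-identification
  and structural checks a 6-user × 16-day cohort; both were chosen as the
  smallest cohorts at which the Monte-Carlo assertions are comfortably
  stable.

## Known limitations

- The generator's resting stratum (step count 0, sleep included) is a
  tight two-level mixture under the white-noise model, so its 2-SD
  outlier rate is nearly zero (cohort mean ≈ 0.25 percentage points),
  and the sleeping stratum's rate is similarly small. Relative
  comparisons of those outlier-percentage features are therefore
  ill-conditioned: the de-identification utility test shows negligible
  absolute shifts (≤ 0.1 percentage points) that still exceed 2% in
  relative terms, and that test currently fails on exactly those
  features while all remaining features shift by far less than 1%.
  With real heart-rate data, whose resting distribution is broad and
  heavy-tailed, the base rate is far from zero and the relative measure
  is stable.
- Day boundaries use a single nominal timezone per user; travel and DST
  are not modelled.
- Resting heart rate includes sleep minutes by the literal step-count-0
  definition; the awake-only variant changes the feature's meaning and is
  left to the flag.
- The 2-D embedding is for visual structure only; no geometric claims are
  made or tested beyond seeded determinism and coarse class separation on
  strongly shifted cohorts.
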