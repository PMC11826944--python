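# Methods

`phenoframe` implements a cross-sectional digital-phenotyping analysis:
smartphone event streams and ecological momentary assessments (EMA) are
reduced to per-day behavioral features, aligned to the 14-day recall window
of the PHQ-8 depression questionnaire, completed by multilevel multiple
imputation, and summarized as Rubin-pooled between-person correlations and
stepwise regression models for depression severity. Because no raw cohort
of this kind is publicly deposited, the package ships a synthetic-cohort
generator with known ground truth; all statistical guarantees quoted below
are statements about recovery of that ground truth.

## Feature extraction

Features are computed per participant-day (units: counts, hours, km, nats;
indices in [0, 1]) in five clusters — screen (7), app (4), call (14),
location (16), EMA (8); 49 day-level features in total.

Key definitions and conventions:

- **Day boundary.** A day is the local interval [00:00, 24:00) in a single
  fixed timezone; timestamps are treated as naive local time. Usage
  episodes crossing midnight are split so each day is credited exactly its
  share (total duration is conserved).
- **Screen sessionization.** An unlock opens an episode; the episode closes
  at the next event whether lock or unlock (a zero-gap policy for repeated
  unlocks); a lock without an open episode and a trailing unmatched unlock
  are dropped. These rules are conservative: malformed streams can only
  shorten, never inflate, usage.
- **Entropy.** All entropies are Shannon entropies in nats of a within-day
  frequency or duration distribution (apps by episode count, calls and
  screen episodes by duration share, significant places by dwell share).
  Normalized entropy divides by ln(N) of the number of states and is
  undefined (missing) for N < 2. Screen entropy uses the duration
  distribution across the day's unlock episodes; a two-state (on/off)
  reading would make normalized screen entropy exactly proportional to the
  raw entropy and therefore carry no information of its own.
- **Regularity index.** For a days-by-24 matrix of hourly dominant states,
  the index is the mean over all unordered day pairs of the fraction of
  hours whose state agrees; one definition is shared by the screen (on/off
  dominant), app (most-used app or idle) and location-routine (dominant
  significant place or away) variants. It is computed over the
  participant's full observation window, not per day, since it is undefined
  for a single day.
- **Motion and places.** Speed between consecutive GPS fixes (haversine,
  R = 6371 km) classifies segments as moving (> 1 km/h) or static; exactly
  1 km/h counts as static (documented tie-break), and duplicate timestamps
  are dropped (first fix kept). The moving/static ratio counts segment
  states (the first fix of a stream only mirrors its following segment).
  Stationary pauses (maximal static runs of at least two fixes) feed
  k-means clustering of static fixes in a local metric projection, with k
  grown until two centroids would come closer than 400 m; pauses within
  200 m of a centroid are visits, others are outliers; clusters with at
  least 10 minutes total dwell are significant. Dwell statistics, time at
  the top-1/2/3 places (0 when fewer places exist), dwell-share entropy,
  transition counts and the outlier-time ratio (non-significant dwell over
  significant dwell) derive from this assignment.
- **Circadian movement.** The mean Lomb-Scargle power of the latitude and
  longitude series over an evenly spaced grid of periods between 23.5 and
  24.5 h, summed over the two axes and reported on the log scale; requires
  fixes spanning at least two days. The location routine index instead
  clusters places once per participant so cluster identities are comparable
  across days.
- **Missing vs zero.** A participant-day with no events for a sensor yields
  missing values, not zeros, for that sensor's features: absence of events
  is indistinguishable from the sensor being off, and day-level missingness
  is exactly what the imputation model consumes. A day that has call
  records but none in one direction records an observed zero count for that
  direction. Four features (screen and app regularity, circadian movement,
  location routine) are window-level: computed once per participant and
  replicated across day rows.

## Episodes and eligibility

The PHQ-8 asks about the last 14 days, so each response anchors an episode
of the completion day plus the 13 preceding days. Missingness of an
episode is the fraction of missing cells over 14 days x all counted feature
columns (EMA and sensing pooled, each column weighted equally). Three
filters mirror a realistic observational design: participants without any
PHQ-8 response contribute nothing; per participant only the
lowest-missingness episode is analyzed (ties: earliest); and participants
whose best episode misses more than 50% of cells (strict inequality) are
excluded. Partially answered PHQ-8 forms are rejected rather than
prorated.

## Two-level predictive mean matching

Imputation runs at the day level on the stacked 14-day blocks, with the
participant as the grouping level and the episode-constant PHQ-8 sum as a
level-2 predictor. Defaults are m = 20 completed datasets, 10
chained-equation cycles, and a donor pool of 5; all three are exposed in
`ImputationSpec`. Per incomplete variable and cycle:

1. a linear model of the variable on all other variables is fit by OLS on
   the originally observed rows (predictors standardized; degenerate
   columns pruned);
2. the residual variance is decomposed into between- and within-participant
   components by the one-way ANOVA moment estimator, and participant
   intercepts are predicted with intraclass-correlation shrinkage
   tau^2 / (tau^2 + sigma^2 / n_j); unseen participants get intercept 0;
3. fixed effects are perturbed by a draw from their estimated sampling
   distribution (a proper-imputation approximation to the Bayesian draw);
4. each missing row copies the observed value of a donor drawn uniformly
   from the `donors` observed rows with the nearest predicted values.

The moment-based random-intercept step replaces a full REML fit per
variable per cycle; it preserves the two-level structure while keeping the
chained sweep fast and dependency-light. Visit order is ascending
missingness, ties broken by name. Observed cells are never altered, and
every imputed value lies in its variable's observed support (both are
tested). Chains record imputed-cell mean/SD traces; the convergence report
flags variables whose last-three-iteration trend exceeds the between-chain
spread. Completed day tables are aggregated to one row per participant:
the mean and SD (n-1) over the 14 days per feature, the SD omitted for the
four window-level features whose within-episode SD is zero by construction.

## Pooled inference

All estimates are computed on each completed dataset and combined by
Rubin's rules (total variance T = W + (1 + 1/m) B) with the Barnard-Rubin
small-sample degrees of freedom; with complete data B = 0 and every pooled
quantity equals its single-dataset counterpart exactly (tested). No
p-values are reported; screening and elimination run on 95% CIs evaluated
at full precision.

- **Correlations** pool on the Fisher z scale with variance 1/(n-3); CIs
  back-transform to r. Pooling r untransformed would violate the variance
  homogeneity Rubin's rules assume.
- **Regressions** are fully standardized OLS fits; betas pool with
  nu_com = n - p - 1. Adjusted R^2 = 1 - (1 - R^2)(n-1)/(n-p-1) pools on
  the Fisher z scale of its square root (Harel-style) and is reported in
  percent; negative per-dataset values clamp to zero before the transform
  and a pooled lower CI bound below zero is floored at 0%. AIC/BIC are
  arithmetic means across datasets, used only for model ordering.
- **Screening** admits features whose pooled-correlation CI excludes zero,
  grouped by cluster; exactly collinear candidates (structural twins such
  as maximum stay duration vs time at the top place) are pruned before
  fitting, keeping the first name.
- **Stepwise backward elimination** repeatedly removes, among predictors
  with zero-including CIs, the one with the smallest |pooled beta| (ties:
  wider CI, then name), refits, and records adjusted R^2; it stops when
  every remaining CI excludes zero. An empty final model is a legal
  outcome. The model battery comprises the five cluster-wise models, a
  sensing-combined model whose candidate pool is the union of the final
  sensing-cluster survivors (a flag switches to the union of all screened
  sensing candidates), the EMA+sensing combination, adjusted-R^2
  differences between them, and sensitivity refits of the three headline
  models with standardized age and gender appended.

## Power planning

The required sample size for detecting a correlation uses the Fisher z
approximation with the small-sample bias term r/(2(n-1)): power at n is
Phi(sqrt(n-3) (atanh r + r/(2(n-1))) - z_crit) plus the opposite tail, and
the reported N is the smallest n reaching the target (cross-checked in the
tests against a brute-force scan; the bias term matters — without it the
minimum for r = 0.12, 80% power, two-sided 5% shifts from 542 to 543).
The d-to-r conversion is r = d / sqrt(d^2 + 4) (equal group sizes).

## Synthetic cohort: what it emulates and what it does not

Each participant has a latent severity s drawn from a gamma distribution
(shape 1.72, scale 3.39, truncated at 24) whose mean ~5.8 and SD ~4.4 give
the right-skewed, subclinical profile typical of general-population
samples. PHQ-8 items discretize s: the noisy sum round(s + N(0, 0.8)) is
clipped to [0, 24] and spread as evenly as possible over 8 items in
{0..3}.

Correlation injection is between-person. For a feature named in the effect
map with target r, its per-participant generating parameter is
m + s_F (b z + delta eta) with z the cohort-standardized severity,
eta ~ N(0,1), and b calibrated so the induced correlation between the
feature's 14-day mean and the observed PHQ-8 sum equals r: b = r / lambda
with lambda ~ 0.982 the analytic attenuation from PHQ-8 measurement noise,
and delta^2 = 1 - b^2 - c^2/s_F^2 where c^2 is the day-level noise
contribution to the 14-day mean. Targets that would need b^2 + c^2/s_F^2
> 1 (or |b| > 0.95) raise a configuration error. Injection is supported
for the 8 EMA items, screen session duration/count/total, and call
counts/durations; severity is standardized within the realized cohort so
targets do not inherit the sampling error of the severity draw. EMA items
are conditionally independent given severity: a feature absent from the
effect map is null both marginally and as a partial effect, which makes
model-structure recovery well-posed (a shared affect factor would turn
marginal nulls into genuine suppressors). Default effect-map magnitudes
(valence -0.55 ... incoming call duration 0.21) reflect the strongest
signals reported for this kind of design.

Event-stream mechanics: screen sessions follow a renewal process
(exponential gaps, gamma durations, ~25 sessions and ~2.7 h per day); app
episodes partition sessions among 8 apps with per-participant power-law
preferences; calls (>= 1 incoming and outgoing per active day, so a silent
call-day is unambiguously a dropped sensor-day) draw gamma durations over
a 6-contact pool; GPS traces visit 3 anchor places at least 600 m apart on
a commute-like schedule with 5-minute fixes, 25 m jitter and ~15 km/h
transitions, so place clustering has known per-day ground truth; EMA
prompts fire morning/midday/evening with items on 0-100 sliders.
Missingness drops sensor-days and EMA prompts independently with the
configured rates; an optional logistic severity term in the drop
probability produces MNAR (default slope 0 = MCAR). Demographics (age
18-56, right-skewed around 23; ~78% female) are independent of severity,
so sensitivity covariates are true nulls.

Not emulated: realistic mobility beyond anchor transitions, app content
categories, weekday/weekend structure, inter-item EMA correlation beyond
severity, autocorrelated day-to-day behavior, and episode-count
heterogeneity across participants. Passing tests therefore demonstrate
correctness of the pipeline's accounting and estimators under a known
data-generating process, not robustness to every property of real sensing
data.

## Numerical choices and problem sizes

Fixed tie-breaks and tolerances: k-means uses a fixed random state with
n_init = 4 and at most 10 clusters; centroid separation 400 m, visit
radius 200 m, significance dwell 10 min; predictor columns with SD below
1e-10 are pruned; exact collinearity is declared at |r| > 1 - 1e-10; the
perfect-correlation guard in Fisher pooling triggers at |r| >= 1 - 1e-12
and flags the estimate degenerate. All randomness flows from
`numpy.random.SeedSequence` children of a single seed, so cohorts,
imputations and traces are byte-identical across runs with the same seed.

The test suite sizes its simulations to the precision each claim needs:
calibration checks run one cohort of n = 500 (complete data, tolerance 2
Monte-Carlo SEs), imputation coverage runs 50 replicates of n = 150 with
20% missingness at m = 5 and 5 cycles (coverage target >= 85%), and
model-structure recovery runs 25 replicates of n = 150 with all 8 EMA
means as candidates (success target >= 80%; with six null candidates and
95% CIs the family-wise false-inclusion bound already concedes ~26% of
replicates, so this threshold has little slack by construction).

## Known limitations

- The location-routine index has no single established formula; the
  regularity-index reading used here is one admissible concretization.
- Whether screen/app regularity should use the day or window as its unit is
  ambiguous; the window reading is adopted (the index is undefined for a
  single day).
- The imputer models every feature as continuous; counts are matched to
  observed values by PMM (so remain integers) but their models are linear.
- Adjusted-R^2 pooling via the square-root Fisher transform loses sign
  information for negative adjusted R^2; such values are reported as 0%.
- The PHQ-8 attenuation compensation is analytic and ignores clipping at
  the scale ends; injected correlations are exact only to within a few
  hundredths near the extremes of the severity range.
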