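# phenoframe

Smartphone digital-phenotyping pipeline for depression severity: from raw
event streams (screen lock/unlock, app foreground episodes, call records,
GPS fixes) and ecological momentary assessments (EMA) to per-day behavioral
features, 14-day PHQ-8 episodes, multilevel multiple imputation, and
Rubin-pooled correlation and regression models.

**Who it is for.** Researchers analyzing passive mobile-sensing studies of
depression (or planning one) who need a tested, reproducible implementation
of the standard analysis chain — and a synthetic cohort generator with known
ground truth to validate every stage, since raw cohorts of this kind are
rarely shareable.

## The analysis in brief

1. **Features** (49 per day, five clusters): screen usage sessions
   (count, duration sum/mean/max, duration entropy, regularity), app usage
   (episode count, mean duration, frequency entropy, regularity), calls
   (count, distinct contacts, duration aggregates and entropy per
   direction), location (haversine distance, log location variance,
   moving/static ratio, significant places from k-means stay-point
   clustering with 400 m separation / 200 m visits / 10 min significance,
   dwell statistics, location entropy, circadian movement via Lomb-Scargle
   24 h-band power, routine index, transitions, outlier time) and daily EMA
   means (valence, arousal, stress, sleep, social quality/quantity,
   nutrition, physical activity on 0-100 sliders).
2. **Episodes**: each PHQ-8 response (8 items, 0-3) anchors the 14-day
   block it asks about; per participant only the lowest-missingness episode
   is kept, and participants with more than 50% missing cells are excluded.
3. **Imputation**: two-level predictive mean matching with participant
   random intercepts, chained equations (default m = 20 datasets, 10
   cycles), then aggregation to episode level (mean and SD over 14 days).
4. **Inference**: between-person Pearson correlations pooled on the Fisher
   z scale by Rubin's rules with Barnard-Rubin degrees of freedom
   (T = W + (1 + 1/m)B); CI-screened candidates feed stepwise backward
   elimination per cluster, sensing-combined and EMA+sensing models, with
   pooled standardized betas, adjusted R² (percent, pooled via the
   sqrt-Fisher transform), AIC/BIC, and age/gender sensitivity refits. No
   p-values anywhere — estimates travel with 95% CIs.
5. **Planning**: d-to-r conversion (r = d/√(d²+4)) and required N for
   detecting a correlation under the Fisher z model with small-sample bias
   term.

## Worked example

Generate a cohort with missing data, run the pipeline, pool a correlation
(`examples/03_impute_and_pool.py`):

```python
from phenoframe import (CohortConfig, ImputationSpec, generate_cohort,
                        extract_day_features, build_analysis_set,
                        impute_episodes, pooled_correlation)

cfg = CohortConfig(n_participants=80, seed=3, sensors=("screen", "ema"),
                   effect_map={"screen_duration_mean": 0.4, "ema_valence": -0.55},
                   missing_rate_day=0.2, missing_rate_ema=0.2)
cohort = generate_cohort(cfg)
table, report = build_analysis_set(cohort.phq8,
                                   extract_day_features(cohort.to_bundle()))
stack = impute_episodes(table, ImputationSpec(m=5, iterations=5, seed=4))
est = pooled_correlation(stack.tables, "screen_duration_mean_mean", "phq8_sum")
```

This prints:

```
eligibility: 80/80 participants retained (> 50% missing excluded)
imputed m=5 datasets; convergence flags: 4
screen_duration_mean_mean: pooled r = +0.412 (95% CI +0.206 to +0.584); injected +0.40
ema_valence_mean: pooled r = -0.548 (95% CI -0.687 to -0.370); injected -0.55
```

The generator injected between-person correlations of +0.40 (mean screen
session duration) and −0.55 (EMA valence) with the PHQ-8 sum; despite 20%
of sensor-days and EMA prompts being dropped, the imputation-then-pooling
chain recovers both within its confidence intervals. Study planning
(`examples/05_power_planning.py`):

```
standardized mean difference d = 0.24 corresponds to r = 0.1191 (~0.12)
required N for 80% power (two-sided alpha = 5%): 542
power at N=107 (an exploratory-study scale): 0.235
```

The other examples cover cohort generation (`01`), feature extraction
(`02`) and the full stepwise model battery with sensitivity refits (`04`).
A thin CLI mirrors the stages: `phenoframe synth | features | impute |
infer | plan`.

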