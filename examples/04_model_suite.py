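"""Cluster-wise and combined stepwise regression models for severity.

Screens features by pooled-correlation CIs, runs backward elimination per
cluster, then the sensing-combined and EMA+sensing models, and reports
pooled standardized betas, adjusted R^2 (percent, with CI) and the age and
gender sensitivity refits.
"""

from phenoframe import (
    CohortConfig,
    ImputationSpec,
    build_analysis_set,
    extract_day_features,
    generate_cohort,
    impute_episodes,
    run_model_suite,
)

cfg = CohortConfig(n_participants=120, seed=5, sensors=("screen", "app", "calls", "ema"))
cohort = generate_cohort(cfg)
table, _ = build_analysis_set(cohort.phq8, extract_day_features(cohort.to_bundle()))
stack = impute_episodes(table, ImputationSpec(m=2, iterations=1, seed=6))

suite = run_model_suite(stack.tables, demographics=cohort.participants)
for name in ("ema", "screen", "call", "sensing", "combined"):
    m = suite["models"][name]
    print(f"\n[{name}] adjusted R^2 = {m.adj_r2.estimate:.2f}% (95% CI {m.adj_r2.ci[0]:.2f} to {m.adj_r2.ci[1]:.2f}), AIC {m.aic:.1f}")
    for pred, est in sorted(m.predictors.items(), key=lambda kv: -abs(kv[1].estimate)):
        print(f"    {pred:35s} beta {est.estimate:+.2f} ({est.ci[0]:+.2f} to {est.ci[1]:+.2f})")
print("\nadjusted R^2 differences:", {k: (round(v, 2) if v is not None else None) for k, v in suite["deltas"].items()})
for name, rep in suite["sensitivity"].items():
    cis = {c: f"({e.ci[0]:+.2f} to {e.ci[1]:+.2f})" for c, e in rep.covariates.items()}
    print(f"sensitivity [{name}]: age {cis['age']}, gender {cis['gender']}")
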