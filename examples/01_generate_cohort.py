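"""Generate a small synthetic cohort and look at its ground truth.

The generator draws a latent depression severity per participant from a
right-skewed distribution (PHQ-8 scale, subclinical on average) and emits
raw smartphone event streams whose features correlate with severity at the
configured targets.
"""

from phenoframe import CohortConfig, generate_cohort
from phenoframe.episodes import phq8_descriptives

cfg = CohortConfig(n_participants=40, seed=1)
cohort = generate_cohort(cfg)

items = cohort.phq8[[f"item_{k}" for k in range(1, 9)]]
desc = phq8_descriptives(items.sum(axis=1))
print(f"participants: {cfg.n_participants}, days each: {cfg.total_days}")
print(
    f"PHQ-8: mean {desc['mean']:.2f}, SD {desc['sd']:.2f}, "
    f">=10 cutoff: {desc['n_above_cutoff']} ({desc['pct_above_cutoff']}%)"
)
for stream in ("screen", "app", "calls", "gps", "ema"):
    print(f"  {stream:>6}: {len(getattr(cohort, stream)):7d} rows")
print("injected feature-severity correlations:", cohort.truth["effect_map"])
# cohort.write("scratch/cohort") would emit the delimited-text files
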