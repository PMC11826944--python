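"""Extract the per-day behavioral feature table from raw event streams.

Each row is one participant-day; empty cells mark sensor-days on which the
stream produced no events (the unit of the downstream missing-data model).
"""

from phenoframe import CohortConfig, extract_day_features, generate_cohort
from phenoframe.features import feature_dictionary

cohort = generate_cohort(CohortConfig(n_participants=5, seed=2))
day = extract_day_features(cohort.to_bundle())

print(f"day table: {day.shape[0]} participant-days x {day.shape[1] - 2} features")
cols = ["screen_episode_count", "screen_duration_sum", "call_incoming_count", "total_distance", "n_significant_clusters", "ema_valence"]
print(day[["participant_id", "date"] + cols].head(6).to_string(index=False))
clusters = {}
for entry in feature_dictionary():
    clusters.setdefault(entry["cluster"], []).append(entry["name"])
print("features per cluster:", {k: len(v) for k, v in clusters.items()})
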