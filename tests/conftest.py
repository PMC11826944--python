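import pytest

from phenoframe.episodes import build_analysis_set
from phenoframe.features import extract_day_features
from phenoframe.impute import aggregate_to_episode
from phenoframe.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Complete-data cohort with every sensor, small enough for unit tests."""
    return generate_cohort(CohortConfig(n_participants=12, seed=7))


@pytest.fixture(scope="session")
def small_day_table(small_cohort):
    return extract_day_features(small_cohort.to_bundle())


@pytest.fixture(scope="session")
def small_analysis(small_cohort, small_day_table):
    """Stacked 14-day analysis table (participant, date, phq8_sum, features)."""
    table, report = build_analysis_set(small_cohort.phq8, small_day_table)
    return table, report


@pytest.fixture(scope="session")
def medium_cohort():
    """Larger complete cohort without GPS (fast extraction) for inference."""
    return generate_cohort(
        CohortConfig(n_participants=60, seed=42, sensors=("screen", "app", "calls", "ema"))
    )


@pytest.fixture(scope="session")
def episode_tables(medium_cohort):
    """Single complete episode-level table (no missingness, m = 1)."""
    day = extract_day_features(medium_cohort.to_bundle())
    table, _ = build_analysis_set(medium_cohort.phq8, day)
    return [aggregate_to_episode(table)]
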