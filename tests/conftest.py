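import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sepsisval import (
    alert_evaluation,
    sepsis_labeler,
    sofa_engine,
    synthetic_cohort as sc,
)

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_cohort():
    """A moderate synthetic cohort at the emulated study conditions, with the
    full pipeline already run: (cohort, truth, sofa_series, labels,
    first_alerts). Session-scoped because several modules analyse it."""
    config = sc.ScenarioConfig(n_encounters=2000, seed=3)
    cohort, truth = sc.generate_cohort(config)
    series = sofa_engine.compute_sofa_series(cohort.observations, cohort.encounters)
    labels = sepsis_labeler.label_cohort(series, cohort.orders, encounters=cohort.encounters)
    first_alerts = alert_evaluation.extract_fired_alerts(cohort.alerts)
    return cohort, truth, series, labels, first_alerts


def make_sofa_series(encounter_id: str, totals, start="2023-03-01T00:00:00+00:00"):
    """Minimal single-encounter SOFA series with the given total trajectory
    (sub-scores collapsed into 'coagulation' for simplicity; labeling only
    reads 'total')."""
    times = pd.date_range(start=start, periods=len(totals), freq="15min", tz="UTC")
    df = pd.DataFrame({"encounter_id": encounter_id, "grid_time": times, "total": totals})
    return df


def make_orders(encounter_id: str, kinds, when="2023-03-01T01:00:00+00:00"):
    return pd.DataFrame(
        {
            "encounter_id": encounter_id,
            "timestamp": pd.to_datetime([when] * len(kinds), utc=True),
            "kind": list(kinds),
        }
    )
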