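"""Shared fixtures: one small synthetic cohort reused across test modules.

The cohort is deliberately small (6 users x 16 days) but has a clear
phenotype effect, so the full chain from raw events to user features is
exercised once per session and the products are shared.
"""

import pandas as pd
import pytest

import wearpipe as wp

SEED = 11


@pytest.fixture(scope="session")
def effect():
    return wp.EffectSpec(rest_hr_delta=10.0, missing_rate=0.05)


@pytest.fixture(scope="session")
def cohort(effect):
    return wp.generate_cohort(6, effect, seed=SEED, n_days=16)


@pytest.fixture(scope="session")
def minutes(cohort):
    table, _reports = wp.preprocess_events(cohort.events)
    return table


@pytest.fixture(scope="session")
def daily(minutes):
    return wp.extract_daily_features(minutes)


@pytest.fixture(scope="session")
def user_features(daily, cohort):
    filtered, _report = wp.filter_cohort(daily, cohort.labels, wp.PipelineParams())
    return wp.aggregate_users(filtered)


@pytest.fixture()
def tiny_events():
    """Three well-formed heart-rate events for one user."""
    return pd.DataFrame(
        {
            "user_id": ["u1", "u1", "u1"],
            "stream": ["heart_rate"] * 3,
            "timestamp": pd.to_datetime(
                ["2019-01-01T00:00:10Z", "2019-01-01T00:00:40Z", "2019-01-01T00:01:05Z"]
            ),
            "value": [60.0, 62.0, 70.0],
            "unit": ["bpm"] * 3,
        }
    )
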