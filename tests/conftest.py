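import pandas as pd
import pytest

from tpdscan import (
    DayWindow,
    InjectedPair,
    SimulationConfig,
    compute_counts,
    simulate,
    validate_cohort,
)


@pytest.fixture
def worked_cohort():
    """Three-person hand-enumerable cohort.

    P1: drug A at day 100, condition Y at day 110 (offset +10).
    P2: drug A at day 100, no Y.
    P3: drug B at day 100, Y at day 50 (offset -50, pre-index).
    All observed over days 0..400.
    """
    exposures = pd.DataFrame(
        {"person_id": [1, 2, 3], "drug_id": ["A", "A", "B"], "day": [100, 100, 100]}
    )
    conditions = pd.DataFrame(
        {"person_id": [1, 3], "condition_id": ["Y", "Y"], "day": [110, 50]}
    )
    observation = pd.DataFrame(
        {"person_id": [1, 2, 3], "start_day": [0, 0, 0], "end_day": [400, 400, 400]}
    )
    return validate_cohort(exposures, conditions, observation)


@pytest.fixture
def worked_store(worked_cohort):
    return compute_counts(
        worked_cohort, [DayWindow(1, 30), DayWindow(-180, -1)], mode="distinct"
    )


@pytest.fixture
def empty_cohort():
    return validate_cohort(
        pd.DataFrame(columns=["person_id", "drug_id", "day"]),
        pd.DataFrame(columns=["person_id", "condition_id", "day"]),
        pd.DataFrame(columns=["person_id", "start_day", "end_day"]),
    )


def small_random_cohort(seed: int, n_persons: int = 200):
    """Desk-scale random cohort used for oracle-equivalence checks."""
    config = SimulationConfig(
        n_persons=n_persons,
        observation_days=400,
        n_drugs=5,
        n_conditions=8,
        exposure_probability=0.4,
        baseline_daily_rate=0.003,
        seed=seed,
        pre_margin_days=180,
        post_margin_days=30,
    )
    cohort, _ = simulate(config)
    return cohort


@pytest.fixture
def injected_config():
    """Ten positive pairs (rate ratio 10 in days 1-30) among 10x20 concepts."""
    pairs = tuple(InjectedPair(d, 100 + d, 10.0, 1, 30) for d in range(1, 11))
    return SimulationConfig(
        n_persons=800,
        observation_days=240,
        n_drugs=10,
        n_conditions=20,
        exposure_probability=0.5,
        baseline_daily_rate=0.001,
        injected_pairs=pairs,
        seed=3,
        pre_margin_days=180,
        post_margin_days=30,
    )
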