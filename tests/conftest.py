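import numpy as np
import pytest

from crowddev import (
    CohortSpec,
    ObserverModel,
    Participant,
    PipelineConfig,
    QuestConfig,
    run_session,
)
from crowddev.session_io import simulate_cohort_trials
from crowddev.observer import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def observer():
    """A mid-range observer: threshold 2', moderate slope, no lapses."""
    return ObserverModel(threshold_gap=2.0, slope_sigma=0.6)


@pytest.fixture
def participant(observer):
    return Participant(
        id="P000",
        age=6.0,
        group="5-6",
        observers={
            "unflanked": observer,
            "flanked_same": ObserverModel(3.0, 0.9),
            "flanked_different": ObserverModel(2.5, 0.75),
        },
    )


@pytest.fixture(scope="session")
def session_log():
    """One participant's full three-condition session (2 blocks each)."""
    p = Participant(
        id="P000",
        age=6.0,
        group="5-6",
        observers={
            "unflanked": ObserverModel(2.0, 0.6),
            "flanked_same": ObserverModel(3.0, 0.9),
            "flanked_different": ObserverModel(2.5, 0.75),
        },
    )
    return run_session(
        p,
        ["flanked_same", "unflanked", "flanked_different"],
        2,
        np.random.default_rng(777),
        QuestConfig(),
    )


@pytest.fixture(scope="session")
def small_cohort_trials():
    """A compact simulated cohort (trials + spec), reused by slow-ish tests."""
    spec = CohortSpec(
        groups=(
            ("3-4", 3.0, 5.0, 5),
            ("7-8", 7.0, 9.0, 5),
            ("adult", 18.0, 38.0, 6),
        ),
        seed=99,
    )
    config = PipelineConfig(cohort=spec, seed=99, conditions=("unflanked", "flanked_same"))
    trials = simulate_cohort_trials(generate_cohort(spec), config)
    return spec, config, trials
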