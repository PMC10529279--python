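import numpy as np
import pytest

from neosuction.config import AnalysisConfig
from neosuction.synthetic_cohort import ScenarioConfig, generate_cohort
from neosuction.types import (
    AmnioticFluid,
    EpisodeRecord,
    EventKind,
    HRSample,
    IntervalEvent,
    Outcome,
    Sex,
)


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-newborn default-scenario cohort with truths, shared per session."""
    scenario = ScenarioConfig(n_newborns=30, seed=2024)
    return generate_cohort(scenario)


def make_episode(
    events=None,
    hr=None,
    newborn_id="NB_T",
    outcome=Outcome.SURVIVED,
    beats=None,
) -> EpisodeRecord:
    """Hand-built episode with a flat 150 bpm HR trace unless overridden."""
    if hr is None:
        hr = [HRSample(float(t), 150.0) for t in range(0, 300)]
    return EpisodeRecord(
        newborn_id=newborn_id,
        outcome=outcome,
        birthweight_g=3100.0,
        ga_weeks=38.0,
        sex=Sex.MALE,
        amniotic_fluid=AmnioticFluid.CLEAR,
        first_hr_bpm=150.0,
        ventilated_flag=True,
        events=list(events or []),
        hr_series=list(hr),
        beats=beats,
    )


def suction(start, stop, **kw) -> IntervalEvent:
    return IntervalEvent(EventKind.SUCTION_INSERTION, start, stop, **kw)


def vent(start, stop) -> IntervalEvent:
    return IntervalEvent(EventKind.VENTILATION, start, stop)
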