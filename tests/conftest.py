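from datetime import datetime, time

import numpy as np
import pytest
from hypothesis import settings

from deskbreak.engine import (
    DecisionContext,
    EngineConfig,
    GeoPoint,
    Poi,
    WeatherObservation,
    WorkSchedule,
)
from deskbreak.simulate import DEFAULT_POIS, ResponseModel, simulate_cohort

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg() -> EngineConfig:
    return EngineConfig()


@pytest.fixture(scope="session")
def schedule() -> WorkSchedule:
    return WorkSchedule(
        work_start=time(8, 0),
        lunch_start=time(12, 30),
        work_end=time(16, 30),
        day_end=time(22, 0),
        workdays=frozenset({6, 0, 1, 2, 3}),  # Sun-Thu
    )


@pytest.fixture
def make_context(schedule):
    """Factory for decision contexts; 2021-12-05 is a Sunday workday."""

    def _make(
        now=datetime(2021, 12, 5, 10, 0),
        trailing_steps=10,
        weather=WeatherObservation(24.0, 50.0, "sunny"),
        pois=DEFAULT_POIS,
        steps_today=3000,
        step_goal=8000,
        user_location=GeoPoint(25.3175, 51.4310),
    ):
        return DecisionContext(
            now=now,
            trailing_steps=trailing_steps,
            weather=weather,
            user_location=user_location,
            pois=tuple(pois),
            schedule=schedule,
            steps_today=steps_today,
            step_goal=step_goal,
        )

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """6+6 participants over 12 days; shared across read-only tests."""
    return simulate_cohort(n_per_arm=6, days=12, seed=7)
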