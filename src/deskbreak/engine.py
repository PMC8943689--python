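"""Decision engine for just-in-time walking prompts.

A JITAI (just-in-time adaptive intervention) is built from decision points,
tailoring variables, decision rules and intervention options.  Here the
decision point is any minute of the (work)day, the tailoring variables are
trailing step count, time of day relative to the work schedule, weather and
nearby points of interest, and the intervention options are 15 message
categories.  :func:`decide` is the pure decision rule tying them together:
a prompt fires when the user has accumulated fewer than
``inactivity_step_threshold`` steps over the trailing ``inactivity_window``
minutes and the cooldown since the last *fired* prompt has elapsed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

EARTH_RADIUS_M = 6_371_000.0

POI_KINDS = frozenset({"restaurant", "gym", "park", "mall"})

#: The 15 intervention-option categories, grouped by time window.
CATEGORIES: tuple[str, ...] = (
    "lunch-walk-out",
    "lunch-walk-near",
    "lunch-indoor",
    "afterwork-park",
    "afterwork-gym",
    "afterwork-mall",
    "afterwork-indoor",
    "endofday-goal-push",
    "endofday-goal-met",
    "endofday-indoor",
    "generic-outdoor-near",
    "generic-outdoor",
    "generic-indoor",
    "generic-stretch",
    "generic-goal",
)

WINDOWS = ("pre_lunch", "pre_endofwork", "pre_endofday", "generic")


class EngineConfig(BaseModel):
    """Tunable thresholds of the decision rules.

    Defaults encode the deployed intervention: prompts after 40 sedentary
    minutes, a 67-step criterion for both inactivity and breaking it, walking
    (500 m) / lunch (1.5 km) / after-work (6 km) destination radii, and the
    winter-Qatar outdoor-weather envelope (13-35 degC, humidity < 90 %).
    """

    inactivity_window: int = 40          # minutes
    inactivity_step_threshold: int = 67  # steps
    break_window: int = 30               # minutes
    break_step_threshold: int = 67       # steps
    walk_radius: float = 500.0           # m
    lunch_radius: float = 1_500.0        # m
    afterwork_radius: float = 6_000.0    # m
    pre_lunch_lead: int = 30             # minutes
    pre_endofwork_lead: int = 60         # minutes
    temp_range: tuple[float, float] = (13.0, 35.0)  # degC, inclusive
    humidity_max: float = 90.0           # %, exclusive
    suitable_forecasts: frozenset[str] = frozenset({"clear skies", "sunny", "cloudy"})
    unsuitable_forecasts: frozenset[str] = frozenset(
        {"windy", "rainy", "thunderstorm", "hailstorm"}
    )
    dismissal_view_threshold: float = 2.0  # seconds

    @model_validator(mode="after")
    def _check(self) -> "EngineConfig":
        if not self.temp_range[0] < self.temp_range[1]:
            raise ValueError("temp_range must satisfy low < high")
        positive = (
            self.inactivity_window, self.inactivity_step_threshold,
            self.break_window, self.break_step_threshold,
            self.walk_radius, self.lunch_radius, self.afterwork_radius,
            self.pre_lunch_lead, self.pre_endofwork_lead,
            self.humidity_max, self.dismissal_view_threshold,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all radii, durations and thresholds must be > 0")
        if self.suitable_forecasts & self.unsuitable_forecasts:
            raise ValueError("a forecast label cannot be both suitable and unsuitable")
        return self

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump()
        data["suitable_forecasts"] = sorted(self.suitable_forecasts)
        data["unsuitable_forecasts"] = sorted(self.unsuitable_forecasts)
        data["temp_range"] = list(self.temp_range)
        Path(path).write_text(yaml.safe_dump({"engine": data}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EngineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw.get("engine", raw))


@dataclass(frozen=True)
class WeatherObservation:
    temperature: float  # degC
    humidity: float     # % in [0, 100]
    forecast: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.humidity <= 100.0:
            raise ValueError(f"humidity must be in [0, 100], got {self.humidity}")


@dataclass(frozen=True)
class GeoPoint:
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True)
class Poi:
    name: str
    kind: str  # restaurant | gym | park | mall
    location: GeoPoint

    def __post_init__(self) -> None:
        if self.kind not in POI_KINDS:
            raise ValueError(f"unknown POI kind {self.kind!r}; expected one of {sorted(POI_KINDS)}")


@dataclass(frozen=True)
class WorkSchedule:
    work_start: time
    lunch_start: time
    work_end: time
    day_end: time
    workdays: frozenset[int]  # datetime.weekday() numbers, Mon=0 .. Sun=6

    def __post_init__(self) -> None:
        if not self.work_start < self.lunch_start < self.work_end < self.day_end:
            raise ValueError("schedule must satisfy work_start < lunch_start < work_end < day_end")

    def is_workday(self, ts: datetime) -> bool:
        return ts.weekday() in self.workdays


@dataclass(frozen=True)
class DecisionContext:
    """Snapshot of every tailoring variable at one decision point."""

    now: datetime
    trailing_steps: int
    weather: WeatherObservation
    user_location: GeoPoint
    pois: tuple[Poi, ...]
    schedule: WorkSchedule
    steps_today: int
    step_goal: int

    def __post_init__(self) -> None:
        if self.trailing_steps < 0:
            raise ValueError("trailing_steps must be >= 0")
        if self.steps_today < 0:
            raise ValueError("steps_today must be >= 0")


@dataclass(frozen=True)
class InterventionDecision:
    fire: bool
    window: str
    weather_suitable: bool
    eligible_pois: tuple[Poi, ...]
    category_id: Optional[str] = None


class UnknownForecastError(ValueError):
    pass


def classify_weather(obs: WeatherObservation, cfg: EngineConfig) -> bool:
    """True iff the observation is suitable for outdoor activity.

    Suitable means temperature within ``cfg.temp_range`` (both bounds
    inclusive), humidity strictly below ``cfg.humidity_max`` and a forecast
    from the suitable set.  A forecast outside both configured sets raises.
    """
    label = obs.forecast.lower()
    if label not in cfg.suitable_forecasts and label not in cfg.unsuitable_forecasts:
        raise UnknownForecastError(f"unknown forecast label {obs.forecast!r}")
    return (
        cfg.temp_range[0] <= obs.temperature <= cfg.temp_range[1]
        and obs.humidity < cfg.humidity_max
        and label in cfg.suitable_forecasts
    )


def is_inactive(trailing_steps: int, cfg: EngineConfig) -> bool:
    """True iff fewer than the threshold steps fell in the trailing window."""
    if trailing_steps < 0:
        raise ValueError("trailing_steps must be >= 0")
    return trailing_steps < cfg.inactivity_step_threshold


def _minutes(t: time) -> int:
    return t.hour * 60 + t.minute


def resolve_time_window(now: datetime, schedule: WorkSchedule, cfg: EngineConfig) -> str:
    """Map a timestamp onto a prompt window.

    ``pre_lunch`` and ``pre_endofwork`` only exist on workdays;
    ``pre_endofday`` applies every day.  On overlap the earlier commitment
    wins: pre_lunch > pre_endofwork > pre_endofday.
    """
    m = now.hour * 60 + now.minute
    workday = schedule.is_workday(now)
    lunch, work_end, day_end = (
        _minutes(schedule.lunch_start),
        _minutes(schedule.work_end),
        _minutes(schedule.day_end),
    )
    if workday and lunch - cfg.pre_lunch_lead <= m < lunch:
        return "pre_lunch"
    if workday and work_end - cfg.pre_endofwork_lead <= m < work_end:
        return "pre_endofwork"
    if day_end - cfg.pre_endofwork_lead <= m < day_end:
        return "pre_endofday"
    return "generic"


def haversine_m(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in meters on a sphere of radius 6,371 km."""
    phi1, phi2 = math.radians(a.latitude), math.radians(b.latitude)
    dphi = phi2 - phi1
    dlam = math.radians(b.longitude - a.longitude)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(h))


def _window_radius(window: str, cfg: EngineConfig) -> float:
    if window == "pre_lunch":
        return cfg.lunch_radius
    if window == "pre_endofwork":
        return cfg.afterwork_radius
    return cfg.walk_radius


def eligible_pois(ctx: DecisionContext, window: str, cfg: EngineConfig) -> tuple[Poi, ...]:
    """POIs within the window-dependent radius, nearest first (ties by name)."""
    radius = _window_radius(window, cfg)
    within = [
        (haversine_m(ctx.user_location, p.location), p.name, p)
        for p in ctx.pois
    ]
    return tuple(p for d, _, p in sorted(within, key=lambda t: (t[0], t[1])) if d <= radius)


def _pick_category(
    window: str,
    suitable: bool,
    pois: Sequence[Poi],
    goal_met: bool,
) -> str:
    """Deterministic 15-leaf category tree over the tailoring variables."""
    has_poi = len(pois) > 0
    if window == "pre_lunch":
        if not suitable:
            return "lunch-indoor"
        return "lunch-walk-out" if has_poi else "lunch-walk-near"
    if window == "pre_endofwork":
        if suitable and has_poi:
            kind = pois[0].kind  # nearest destination steers the suggestion
            if kind == "park":
                return "afterwork-park"
            if kind == "gym":
                return "afterwork-gym"
            return "afterwork-mall"
        return "afterwork-indoor"
    if window == "pre_endofday":
        if goal_met:
            return "endofday-goal-met"
        return "endofday-goal-push" if suitable else "endofday-indoor"
    # generic
    if goal_met:
        return "generic-goal"
    if suitable:
        return "generic-outdoor-near" if has_poi else "generic-outdoor"
    return "generic-indoor" if has_poi else "generic-stretch"


def decide(
    ctx: DecisionContext,
    last_message_time: Optional[datetime],
    cfg: EngineConfig,
) -> InterventionDecision:
    """Evaluate the decision rules at one decision point.

    Pure function of its arguments.  Fires only when the user is inactive and
    at least ``inactivity_window`` minutes have passed since the last fired
    prompt; the cooldown clock is not reset by suppressed decisions.
    """
    window = resolve_time_window(ctx.now, ctx.schedule, cfg)
    suitable = classify_weather(ctx.weather, cfg)
    pois = eligible_pois(ctx, window, cfg)
    cooldown_ok = (
        last_message_time is None
        or ctx.now - last_message_time >= timedelta(minutes=cfg.inactivity_window)
    )
    fire = is_inactive(ctx.trailing_steps, cfg) and cooldown_ok
    category = None
    if fire:
        category = _pick_category(window, suitable, pois, ctx.steps_today >= ctx.step_goal)
    return InterventionDecision(
        fire=fire,
        window=window,
        weather_suitable=suitable,
        eligible_pois=pois,
        category_id=category,
    )
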