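"""Agent-based simulation of sedentary office workers under the intervention.

No raw study data exist, so this module emulates the data-collection setup
end to end: per-minute step traces for each participant-day, the decision
engine running minute-by-minute over those traces, and a probabilistic
response model for each delivered prompt (view time, dismissal, and an
arm-dependent probability of actually breaking the sitting bout with a
67-300-step burst inside the 30-minute evaluation window).

Trace model: a near-zero desk baseline during work hours (including a desk
lunch), walking commutes before and well after work, occasional micro-breaks,
and optional evening leisure walks.  Commute and leisure bursts are placed
outside every possible post-message 30-minute window so that the measured
break rate estimates the generating response probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as date_cls, datetime, time, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import ipaq
from .analytics import LOG_COLUMNS, MessageLogRecord
from .engine import (
    DecisionContext,
    EngineConfig,
    GeoPoint,
    Poi,
    WeatherObservation,
    WorkSchedule,
    decide,
)
from .messages import (
    MessageTemplate,
    RenderError,
    load_bank,
    pick_template,
    poi_free_templates,
    render,
)

STATIC_MESSAGE = "You have been sitting for a while. How about a short walk?"

#: Sunday-Thursday working week (datetime.weekday numbers), as at the study site.
QATAR_WORKDAYS = frozenset({6, 0, 1, 2, 3})

DEFAULT_SCHEDULE = WorkSchedule(
    work_start=time(8, 0),
    lunch_start=time(12, 30),
    work_end=time(16, 30),
    day_end=time(22, 0),
    workdays=QATAR_WORKDAYS,
)

#: Fixed workplace location (Doha) and surrounding points of interest.
WORKPLACE = GeoPoint(25.3175, 51.4310)


def _offset(origin: GeoPoint, dist_m: float, bearing_deg: float) -> GeoPoint:
    b = np.radians(bearing_deg)
    dlat = dist_m * np.cos(b) / 111_320.0
    dlon = dist_m * np.sin(b) / (111_320.0 * np.cos(np.radians(origin.latitude)))
    return GeoPoint(origin.latitude + dlat, origin.longitude + dlon)


DEFAULT_POIS: tuple[Poi, ...] = tuple(
    Poi(name, kind, _offset(WORKPLACE, d, b))
    for name, kind, d, b in [
        ("Spice Route Restaurant", "restaurant", 300, 40),
        ("Corniche Park", "park", 420, 130),
        ("Tower Fitness Gym", "gym", 650, 250),
        ("Seaside Restaurant", "restaurant", 950, 80),
        ("Al Bidda Mall", "mall", 1_250, 200),
        ("Oasis Park", "park", 2_600, 310),
        ("City Centre Mall", "mall", 4_100, 20),
        ("Harbor Gym", "gym", 5_500, 170),
    ]
)

FORECASTS = ("sunny", "clear skies", "cloudy", "rainy", "windy")
FORECAST_P = (0.35, 0.20, 0.25, 0.12, 0.08)


class ResponseModel(BaseModel):
    """How a simulated participant reacts to a delivered prompt.

    Break probabilities default to the realized per-arm break rates of the
    deployed study (context-aware 2781/5228, static 224/1125).
    """

    p_dismiss: float = 0.15
    p_break_given_context_aware: float = 0.532
    p_break_given_static: float = 0.199
    read_view_lognorm_mean: float = 1.5   # of log-seconds above the 2-s floor
    read_view_lognorm_sigma: float = 0.6
    break_steps_range: tuple[int, int] = (67, 300)

    @model_validator(mode="after")
    def _check(self) -> "ResponseModel":
        for name in ("p_dismiss", "p_break_given_context_aware", "p_break_given_static"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.break_steps_range[0] < 67:
            raise ValueError("break bursts must reach the 67-step criterion")
        if self.break_steps_range[0] > self.break_steps_range[1]:
            raise ValueError("break_steps_range must be ordered")
        return self


@dataclass(frozen=True)
class UserProfile:
    user_id: str
    gender: str          # female | male
    age_group: str       # 23-30 | 31-39
    arm: str             # control | intervention
    ipaq_report: ipaq.IpaqReport
    ipaq_category: str   # low | moderate | high
    schedule: WorkSchedule
    step_goal: int
    enrolled_days: int

    def __post_init__(self) -> None:
        if self.enrolled_days < 1:
            raise ValueError("enrolled_days must be >= 1")
        if self.age_group not in ("23-30", "31-39"):
            raise ValueError(f"unknown age_group {self.age_group!r}")


@dataclass
class ActivityTrace:
    user_id: str
    date: date_cls
    steps_per_minute: np.ndarray  # 1,440 non-negative ints

    def __post_init__(self) -> None:
        self.steps_per_minute = np.asarray(self.steps_per_minute, dtype=np.int64)
        if self.steps_per_minute.shape != (1440,):
            raise ValueError("a daily trace must have exactly 1,440 minutes")
        if (self.steps_per_minute < 0).any():
            raise ValueError("step counts must be non-negative")


@dataclass
class CohortData:
    profiles: list[UserProfile]
    traces: list[ActivityTrace]
    logs: list[MessageLogRecord]

    def profiles_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            r = p.ipaq_report
            rows.append(
                {
                    "user_id": p.user_id,
                    "gender": p.gender,
                    "age_group": p.age_group,
                    "arm": p.arm,
                    "ipaq_category": p.ipaq_category,
                    "met_minutes": ipaq.met_minutes(r),
                    "walk_days": r.walk_days, "walk_min": r.walk_min,
                    "mod_days": r.mod_days, "mod_min": r.mod_min,
                    "vig_days": r.vig_days, "vig_min": r.vig_min,
                    "step_goal": p.step_goal,
                    "enrolled_days": p.enrolled_days,
                }
            )
        return pd.DataFrame(rows)

    def traces_frame(self, keep_zeros: bool = False) -> pd.DataFrame:
        """Long format (user_id, date, minute_index, steps); zero-step
        minutes are omitted unless ``keep_zeros`` (readers re-densify)."""
        parts = []
        for tr in self.traces:
            steps = tr.steps_per_minute
            idx = np.arange(1440) if keep_zeros else np.nonzero(steps)[0]
            parts.append(
                pd.DataFrame(
                    {
                        "user_id": tr.user_id,
                        "date": tr.date.isoformat(),
                        "minute_index": idx,
                        "steps": steps[idx],
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    def logs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "user_id": r.user_id,
                "arm": r.arm,
                "sent_at": r.sent_at.isoformat(),
                "msg_type": r.msg_type,
                "category_id": r.category_id or "",
                "framing": r.framing or "",
                "text": r.text,
                "steps_before": r.steps_before,
                "steps_after_30": r.steps_after_30,
                "view_seconds": round(r.view_seconds, 3),
                "explicitly_dismissed": r.explicitly_dismissed,
            }
            for r in self.logs
        ]
        return pd.DataFrame(rows, columns=LOG_COLUMNS)

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "profiles": outdir / "profiles.csv",
            "traces": outdir / "traces.csv",
            "logs": outdir / "logs.csv",
        }
        self.profiles_frame().to_csv(paths["profiles"], index=False)
        self.traces_frame().to_csv(paths["traces"], index=False)
        self.logs_frame().to_csv(paths["logs"], index=False)
        return paths


def _minutes(t: time) -> int:
    return t.hour * 60 + t.minute


def _walk_burst(steps: np.ndarray, start: int, duration: int, rng: np.random.Generator,
                lo: int = 60, hi: int = 100) -> None:
    end = min(start + duration, 1440)
    if start < 0 or start >= 1440:
        return
    steps[start:end] += rng.integers(lo, hi + 1, size=end - start)


def _base_trace(profile: UserProfile, workday: bool, rng: np.random.Generator) -> np.ndarray:
    """Untreated step trace: desk-bound workdays, freer weekends."""
    steps = np.zeros(1440, dtype=np.int64)
    sched = profile.schedule
    ws, we, de = _minutes(sched.work_start), _minutes(sched.work_end), _minutes(sched.day_end)
    if workday:
        # desk noise through work hours (incl. a desk lunch)
        steps[ws:we] += rng.poisson(0.03, size=we - ws)
        # micro-breaks: brief walks to printer/bathroom, too small to count
        # as a sedentary break on their own
        n_micro = rng.poisson((we - ws) / 150)
        for m in rng.integers(ws, we, size=n_micro):
            steps[m] += rng.integers(5, 26)
        # commute in, ending 15 min before work
        dur = int(rng.integers(8, 15))
        _walk_burst(steps, ws - 15 - dur, dur, rng)
        # commute home; starts > break_window after the last possible
        # work-hours prompt so it cannot contaminate a delta window
        _walk_burst(steps, we + 35, int(rng.integers(8, 15)), rng)
        # optional evening leisure walk, finished well before the
        # end-of-day prompt window opens
        if rng.random() < 0.35:
            start = int(rng.integers(we + 70, de - 150))
            _walk_burst(steps, start, int(rng.integers(15, 31)), rng, lo=60, hi=90)
    else:
        for _ in range(int(rng.integers(1, 4))):
            start = int(rng.integers(9 * 60, 20 * 60))
            _walk_burst(steps, start, int(rng.integers(10, 40)), rng, lo=50, hi=90)
        steps[9 * 60: 21 * 60] += rng.poisson(0.05, size=12 * 60)
    return steps


def _view_and_dismissal(model: ResponseModel, rng: np.random.Generator) -> tuple[float, bool, bool]:
    """Returns (view_seconds, explicitly_dismissed, dismissed)."""
    if rng.random() < model.p_dismiss:
        if rng.random() < 0.5:
            return float(rng.uniform(0.0, 5.0)), True, True
        return float(rng.uniform(0.0, 2.0)), False, True
    view = 2.0 + float(rng.lognormal(model.read_view_lognorm_mean, model.read_view_lognorm_sigma))
    return view, False, False


def simulate_day(
    profile: UserProfile,
    weather_by_hour: Sequence[WeatherObservation],
    pois: Sequence[Poi],
    model: ResponseModel,
    engine_cfg: EngineConfig,
    rng: Union[int, np.random.Generator],
    day: date_cls = date_cls(2021, 12, 5),
    bank: Optional[list[MessageTemplate]] = None,
    workplace: GeoPoint = WORKPLACE,
) -> tuple[ActivityTrace, list[MessageLogRecord]]:
    """One participant-day: trace generation with the engine in the loop.

    The engine is evaluated every minute from work start to day end on
    workdays; each fired prompt is logged, and a positive break response
    injects a 1-3-minute step burst uniformly placed in the following
    30-minute window.  ``steps_after_30`` is left missing when the window
    runs past midnight.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if bank is None:
        bank = load_bank()
    sched = profile.schedule
    workday = day.weekday() in sched.workdays
    steps = _base_trace(profile, workday, rng)
    cum = np.cumsum(steps)
    logs: list[MessageLogRecord] = []
    pending: list[tuple[int, int]] = []  # (sent minute, steps_before)

    if workday:
        ws, we, de = _minutes(sched.work_start), _minutes(sched.work_end), _minutes(sched.day_end)
        # decision points: work hours, then the end-of-day goal window; the
        # off-work gap is prompt-free (commute time)
        decision_minutes = list(range(ws, we)) + list(range(max(we, de - engine_cfg.pre_endofwork_lead), de))
        last_fire: Optional[int] = None
        intervention = profile.arm == "intervention"
        for t in decision_minutes:
            trailing = int(cum[t] - (cum[t - engine_cfg.inactivity_window] if t >= engine_cfg.inactivity_window else 0))
            if trailing >= engine_cfg.inactivity_step_threshold:
                continue
            if last_fire is not None and t - last_fire < engine_cfg.inactivity_window:
                continue
            now = datetime.combine(day, time(t // 60, t % 60))
            ctx = DecisionContext(
                now=now,
                trailing_steps=trailing,
                weather=weather_by_hour[t // 60],
                user_location=workplace,
                pois=tuple(pois),
                schedule=sched,
                steps_today=int(cum[t]),
                step_goal=profile.step_goal,
            )
            decision = decide(ctx, None if last_fire is None else
                              datetime.combine(day, time(last_fire // 60, last_fire % 60)),
                              engine_cfg)
            if not decision.fire:
                continue
            last_fire = t
            if intervention:
                tpl = pick_template(bank, decision.category_id, rng)
                try:
                    msg = render(tpl, ctx, decision)
                except RenderError:
                    fallback = poi_free_templates(bank, decision.category_id)
                    msg = render(fallback[int(rng.integers(len(fallback)))], ctx, decision)
                msg_type, category, framing = "context_aware", msg.category_id, msg.msg_type
                text = f"{msg.heading} {msg.body}"
            else:
                msg_type, category, framing, text = "static", None, None, STATIC_MESSAGE
            view, explicit, dismissed = _view_and_dismissal(model, rng)
            p_break = (
                model.p_break_given_context_aware if intervention else model.p_break_given_static
            )
            if not dismissed and rng.random() < p_break:
                total = int(rng.integers(model.break_steps_range[0], model.break_steps_range[1] + 1))
                dur = int(rng.integers(1, 4))  # 1-3 minute burst
                offset = int(rng.integers(1, engine_cfg.break_window - dur + 2))
                burst = rng.multinomial(total, np.full(dur, 1.0 / dur))
                lo = t + offset
                steps[lo:lo + dur] += burst
                cum[lo:lo + dur] += np.cumsum(burst)
                cum[lo + dur:] += int(burst.sum())
            pending.append((t, int(cum[t])))
            logs.append(
                MessageLogRecord(
                    user_id=profile.user_id,
                    arm=profile.arm,
                    sent_at=now,
                    msg_type=msg_type,
                    category_id=category,
                    framing=framing,
                    text=text,
                    steps_before=int(cum[t]),
                    steps_after_30=None,  # filled once the day is complete
                    view_seconds=view,
                    explicitly_dismissed=explicit,
                )
            )

    # finalize steps_after_30 from the completed trace
    final_cum = np.cumsum(steps)
    finalized = []
    for rec, (t, _before) in zip(logs, pending):
        after_idx = t + engine_cfg.break_window
        after = int(final_cum[after_idx]) if after_idx < 1440 else None
        finalized.append(
            MessageLogRecord(
                **{**rec.__dict__, "steps_before": int(final_cum[t]), "steps_after_30": after}
            )
        )
    trace = ActivityTrace(profile.user_id, day, steps)
    return trace, finalized


def _daily_weather(rng: np.random.Generator) -> list[WeatherObservation]:
    base_temp = float(np.clip(rng.normal(24.0, 6.0), 5.0, 45.0))
    humidity = float(np.clip(rng.normal(55.0, 15.0), 10.0, 100.0))
    forecast = str(rng.choice(FORECASTS, p=FORECAST_P))
    hours = []
    for h in range(24):
        diurnal = 4.0 * np.sin((h - 9) / 24 * 2 * np.pi)
        hours.append(WeatherObservation(round(base_temp + diurnal, 1), round(humidity, 1), forecast))
    return hours


# Enrollment-length model: weeks-tier bins with the per-arm proportions
# observed in the deployed study's engagement table.
DROPOUT_BINS = ((7, 21), (22, 42), (43, 66))
DROPOUT_WEIGHTS = {
    "control": (11 / 29, 12 / 29, 6 / 29),
    "intervention": (1 / 29, 12 / 29, 16 / 29),
}


def _draw_enrollment(arm: str, days: int, rng: np.random.Generator) -> int:
    k = int(rng.choice(3, p=DROPOUT_WEIGHTS[arm]))
    lo, hi = DROPOUT_BINS[k]
    lo, hi = min(lo, days), min(hi, days)
    return int(rng.integers(lo, hi + 1))


def _random_ipaq(rng: np.random.Generator) -> ipaq.IpaqReport:
    return ipaq.IpaqReport(
        walk_days=int(rng.integers(0, 8)),
        walk_min=float(rng.choice([0, 10, 15, 20, 30, 45, 60])),
        mod_days=int(rng.integers(0, 5)),
        mod_min=float(rng.choice([0, 0, 20, 30, 45])),
        vig_days=int(rng.integers(0, 4)),
        vig_min=float(rng.choice([0, 0, 0, 20, 30, 60])),
    )


def simulate_cohort(
    n_per_arm: int,
    model: Optional[ResponseModel] = None,
    engine_cfg: Optional[EngineConfig] = None,
    days: int = 66,
    seed: int = 0,
    start: date_cls = date_cls(2021, 12, 5),
    pois: Sequence[Poi] = DEFAULT_POIS,
) -> CohortData:
    """Simulate a two-arm cohort; fully reproducible under ``seed``.

    IPAQ categories are scored from synthetic questionnaire reports and
    balanced across arms by stratified allocation; per-user enrollment
    lengths follow the engagement-tier dropout model.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    if days < 1:
        raise ValueError("days must be >= 1")
    model = model or ResponseModel()
    engine_cfg = engine_cfg or EngineConfig()
    ss = np.random.SeedSequence(seed)
    root = np.random.default_rng(ss)
    bank = load_bank()

    n = 2 * n_per_arm
    reports = [_random_ipaq(root) for _ in range(n)]
    categories = [ipaq.classify(ipaq.met_minutes(r)) for r in reports]
    alloc_seed = int(root.integers(2**31))
    arms = ipaq.stratified_allocate(categories, seed=alloc_seed)

    weather_rng = np.random.default_rng(ss.spawn(1)[0])
    weather = [_daily_weather(weather_rng) for _ in range(days)]

    profiles: list[UserProfile] = []
    for i in range(n):
        profiles.append(
            UserProfile(
                user_id=f"u{i + 1:03d}",
                gender="female" if root.random() < 0.62 else "male",
                age_group="23-30" if root.random() < 0.724 else "31-39",
                arm=arms[i],
                ipaq_report=reports[i],
                ipaq_category=categories[i],
                schedule=DEFAULT_SCHEDULE,
                step_goal=int(root.choice([6000, 8000, 10000])),
                enrolled_days=_draw_enrollment(arms[i], days, root),
            )
        )

    traces: list[ActivityTrace] = []
    logs: list[MessageLogRecord] = []
    user_seeds = ss.spawn(n)
    for profile, user_ss in zip(profiles, user_seeds):
        rng = np.random.default_rng(user_ss)
        for d in range(profile.enrolled_days):
            day = start + timedelta(days=d)
            trace, day_logs = simulate_day(
                profile, weather[d], pois, model, engine_cfg, rng, day=day, bank=bank
            )
            traces.append(trace)
            logs.extend(day_logs)
    return CohortData(profiles=profiles, traces=traces, logs=logs)
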