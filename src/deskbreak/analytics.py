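"""Derived variables from message logs and step traces.

Turns raw telemetry into the evaluation quantities: a message is *dismissed*
if explicitly dismissed or viewed under 2 s; among non-dismissed messages the
step delta over the 30 minutes after sending decides whether the prompt
*broke* the sitting bout (delta >= 67 steps); app-use duration in weeks maps
each user onto an engagement tier; and per-minute traces yield daily active
minutes.  Contingency tables built here feed the stats battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .engine import EngineConfig
from .stats import ContingencyTable, chi_square, mann_kendall, mann_whitney

LOG_COLUMNS = [
    "user_id", "arm", "sent_at", "msg_type", "category_id", "framing", "text",
    "steps_before", "steps_after_30", "view_seconds", "explicitly_dismissed",
]

TIERS = ("inactive", "semiactive", "active")
FRAMINGS = ("gain_framed", "loss_framed", "self_efficacy")

DEFAULT_ACTIVE_THRESHOLD = 10  # steps/min


@dataclass(frozen=True)
class MessageLogRecord:
    user_id: str
    arm: str  # control | intervention
    sent_at: datetime
    msg_type: str  # context_aware | static
    category_id: Optional[str]
    framing: Optional[str]
    text: str
    steps_before: int
    steps_after_30: Optional[int]  # None when the 30-min window ran off the log
    view_seconds: float
    explicitly_dismissed: bool

    def __post_init__(self) -> None:
        if self.view_seconds < 0:
            raise ValueError("view_seconds must be >= 0")
        if self.steps_after_30 is not None and self.steps_after_30 < self.steps_before:
            raise ValueError("cumulative step counter must be monotone within a day")
        if self.arm == "control" and (
            self.msg_type != "static" or self.category_id is not None or self.framing is not None
        ):
            raise ValueError("control-arm records carry only the static message")


@dataclass(frozen=True)
class DerivedMessageRecord:
    record: MessageLogRecord
    dismissed: bool
    step_delta: Optional[int]
    broke_inactivity: Optional[bool]  # None = not applicable (dismissed/missing)


@dataclass(frozen=True)
class EngagementRecord:
    user_id: str
    enrolled_days: int
    weeks: int
    tier: str


def mark_dismissed(record: MessageLogRecord, cfg: EngineConfig) -> bool:
    """Dismissed = explicitly dismissed, or viewed under the 2-s threshold."""
    return record.explicitly_dismissed or record.view_seconds < cfg.dismissal_view_threshold


def evaluate_break(record: MessageLogRecord, cfg: EngineConfig) -> DerivedMessageRecord:
    """Attach dismissal, step delta and break-of-inactivity flags."""
    dismissed = mark_dismissed(record, cfg)
    if record.steps_after_30 is None:
        return DerivedMessageRecord(record, dismissed, None, None)
    delta = record.steps_after_30 - record.steps_before
    broke = None if dismissed else delta >= cfg.break_step_threshold
    return DerivedMessageRecord(record, dismissed, delta, broke)


def classify_engagement(enrolled_days: int, user_id: str = "") -> EngagementRecord:
    """Engagement tier from days of app use (weeks = ceil(days/7))."""
    if enrolled_days < 0:
        raise ValueError("enrolled_days must be >= 0")
    weeks = math.ceil(enrolled_days / 7)
    tier = "inactive" if weeks <= 3 else ("semiactive" if weeks <= 6 else "active")
    return EngagementRecord(user_id=user_id, enrolled_days=enrolled_days, weeks=weeks, tier=tier)


def daily_active_minutes(
    trace: Union[Sequence[int], "np.ndarray"],
    active_threshold: int = DEFAULT_ACTIVE_THRESHOLD,
) -> int:
    """Minutes of a one-day trace at or above the step threshold."""
    steps = getattr(trace, "steps_per_minute", trace)
    arr = np.asarray(steps)
    if arr.shape != (1440,):
        raise ValueError(f"a daily trace must have exactly 1,440 minutes, got {arr.shape}")
    if (arr < 0).any():
        raise ValueError("step counts must be non-negative")
    return int((arr >= active_threshold).sum())


def build_break_table(
    records: Iterable[DerivedMessageRecord],
    rows: Literal["msg_type", "framing"] = "msg_type",
) -> ContingencyTable:
    """Grouping x {did_not_break, broke} counts over non-dismissed records."""
    kept = [r for r in records if not r.dismissed and r.broke_inactivity is not None]
    if not kept:
        raise ValueError("no non-dismissed records to tabulate")
    if rows == "msg_type":
        levels = ("context_aware", "static")
        key = lambda r: r.record.msg_type
    else:
        levels = FRAMINGS
        key = lambda r: r.record.framing
    present = tuple(lv for lv in levels if any(key(r) == lv for r in kept))
    if not present:
        raise ValueError(f"no records with a known {rows} level")
    counts = tuple(
        (
            sum(1 for r in kept if key(r) == lv and not r.broke_inactivity),
            sum(1 for r in kept if key(r) == lv and r.broke_inactivity),
        )
        for lv in present
    )
    return ContingencyTable(present, ("did_not_break", "broke"), counts)


# --------------------------------------------------------------------------
# DataFrame pipeline (CSV schemas shared with the simulator and CLI)


def read_logs(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"category_id": "string", "framing": "string", "text": "string"})
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"logs file missing columns: {missing}")
    if df.empty:
        raise ValueError("logs file contains no records")
    df["sent_at"] = pd.to_datetime(df["sent_at"])
    df["explicitly_dismissed"] = df["explicitly_dismissed"].astype(bool)
    return df


def write_logs(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, columns=LOG_COLUMNS)


def read_traces(path: Union[str, Path]) -> pd.DataFrame:
    """Long traces (user_id, date, minute_index, steps); zero rows may be omitted."""
    df = pd.read_csv(path, dtype={"user_id": "string"})
    need = {"user_id", "date", "minute_index", "steps"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"traces file missing columns: {sorted(missing)}")
    return df


def derive_frame(logs: pd.DataFrame, cfg: EngineConfig) -> pd.DataFrame:
    """Vectorized dismissal/delta/break derivation over a logs frame."""
    out = logs.copy()
    if (out["view_seconds"] < 0).any():
        bad = out.index[out["view_seconds"] < 0].tolist()[:5]
        raise ValueError(f"negative view_seconds at rows {bad}")
    out["dismissed"] = out["explicitly_dismissed"] | (
        out["view_seconds"] < cfg.dismissal_view_threshold
    )
    out["step_delta"] = out["steps_after_30"] - out["steps_before"]
    if (out["step_delta"].dropna() < 0).any():
        raise ValueError("cumulative step counter must be monotone within a day")
    out["broke_inactivity"] = pd.array(
        np.where(
            out["dismissed"] | out["step_delta"].isna(),
            None,
            out["step_delta"] >= cfg.break_step_threshold,
        ),
        dtype="boolean",
    )
    return out


def break_table_from_frame(
    derived: pd.DataFrame, rows: Literal["msg_type", "framing"] = "msg_type"
) -> ContingencyTable:
    kept = derived[~derived["dismissed"] & derived["broke_inactivity"].notna()]
    if kept.empty:
        raise ValueError("no non-dismissed records to tabulate")
    order = ("context_aware", "static") if rows == "msg_type" else FRAMINGS
    levels = tuple(lv for lv in order if (kept[rows] == lv).any())
    counts = tuple(
        (
            int(((kept[rows] == lv) & ~kept["broke_inactivity"].astype(bool)).sum()),
            int(((kept[rows] == lv) & kept["broke_inactivity"].astype(bool)).sum()),
        )
        for lv in levels
    )
    return ContingencyTable(levels, ("did_not_break", "broke"), counts)


def engagement_frame(profiles: pd.DataFrame) -> pd.DataFrame:
    recs = [classify_engagement(int(d), str(u)) for u, d in zip(profiles["user_id"], profiles["enrolled_days"])]
    return pd.DataFrame(
        {
            "user_id": [r.user_id for r in recs],
            "arm": profiles["arm"].to_numpy(),
            "enrolled_days": [r.enrolled_days for r in recs],
            "weeks": [r.weeks for r in recs],
            "tier": [r.tier for r in recs],
        }
    )


def engagement_table(profiles: pd.DataFrame) -> ContingencyTable:
    """tier x arm counts, rows ordered inactive/semiactive/active."""
    eng = engagement_frame(profiles)
    counts = tuple(
        (
            int(((eng["tier"] == t) & (eng["arm"] == "control")).sum()),
            int(((eng["tier"] == t) & (eng["arm"] == "intervention")).sum()),
        )
        for t in TIERS
    )
    return ContingencyTable(TIERS, ("control", "intervention"), counts)


def active_minutes_frame(
    traces: pd.DataFrame, active_threshold: int = DEFAULT_ACTIVE_THRESHOLD
) -> pd.DataFrame:
    """Per user-day active minutes from the (possibly sparse) long traces."""
    active = traces[traces["steps"] >= active_threshold]
    out = (
        active.groupby(["user_id", "date"], as_index=False)
        .size()
        .rename(columns={"size": "active_minutes"})
    )
    # user-days present in the trace but fully below threshold count as 0
    all_days = traces[["user_id", "date"]].drop_duplicates()
    out = all_days.merge(out, on=["user_id", "date"], how="left").fillna({"active_minutes": 0})
    out["active_minutes"] = out["active_minutes"].astype(int)
    return out.sort_values(["user_id", "date"], ignore_index=True)


def _arm_daily_series(
    am: pd.DataFrame, profiles: pd.DataFrame, arm: str, top_n: int = 6
) -> np.ndarray:
    """Mean daily active minutes over the arm's most engaged users.

    Mirrors the evaluation design: take the ``top_n`` longest-enrolled users
    of the arm and average their active minutes over the first
    min-common-enrollment days.
    """
    users = (
        profiles[profiles["arm"] == arm]
        .sort_values(["enrolled_days", "user_id"], ascending=[False, True])
        .head(top_n)
    )
    common = int(users["enrolled_days"].min())
    frames = []
    for uid in users["user_id"]:
        series = am[am["user_id"] == uid].sort_values("date")["active_minutes"].to_numpy()
        frames.append(series[:common])
    return np.vstack(frames).mean(axis=0)


def analyze(
    logs: pd.DataFrame,
    traces: pd.DataFrame,
    profiles: pd.DataFrame,
    cfg: Optional[EngineConfig] = None,
    active_threshold: int = DEFAULT_ACTIVE_THRESHOLD,
    top_n_engaged: int = 6,
) -> dict:
    """Full evaluation report over a simulated (or real) cohort dataset."""
    cfg = cfg or EngineConfig()
    derived = derive_frame(logs, cfg)
    kept = derived[~derived["dismissed"] & derived["broke_inactivity"].notna()]

    report: dict = {"arms": {}}
    for arm in ("control", "intervention"):
        sub = derived[derived["arm"] == arm]
        subk = kept[kept["arm"] == arm]
        report["arms"][arm] = {
            "n_records": int(len(sub)),
            "n_non_dismissed": int(len(subk)),
            "dismissal_rate": float(sub["dismissed"].mean()) if len(sub) else None,
            "break_rate": float(subk["broke_inactivity"].astype(bool).mean()) if len(subk) else None,
        }

    break_tab = break_table_from_frame(derived, "msg_type")
    chi_break = chi_square(break_tab, yates=True)
    report["break_table"] = [list(r) for r in break_tab.counts]
    report["chi2_break"] = {
        "statistic": chi_break.statistic,
        "df": chi_break.df,
        "p_value": chi_break.p_value,
    }
    if (kept["framing"].notna()).any():
        framing_tab = break_table_from_frame(
            kept[kept["framing"].notna()], "framing"
        )
        chi_fr = chi_square(framing_tab, yates=False)
        report["chi2_framing"] = {
            "statistic": chi_fr.statistic,
            "df": chi_fr.df,
            "p_value": chi_fr.p_value,
        }

    eng_tab = engagement_table(profiles)
    report["engagement_table"] = [list(r) for r in eng_tab.counts]
    try:
        chi_eng = chi_square(eng_tab, yates=False)
        report["chi2_engagement"] = {
            "statistic": chi_eng.statistic,
            "df": chi_eng.df,
            "p_value": chi_eng.p_value,
        }
    except ValueError:  # a tier or arm empty: independence is untestable
        report["chi2_engagement"] = None

    am = active_minutes_frame(traces, active_threshold)
    series = {
        arm: _arm_daily_series(am, profiles, arm, top_n_engaged)
        for arm in ("control", "intervention")
    }
    report["active_minutes"] = {}
    for arm, s in series.items():
        trend = mann_kendall(s)
        report["active_minutes"][arm] = {
            "n_days": int(s.size),
            "mean_daily": float(s.mean()),
            "mann_kendall": {"S": trend.S, "Z": trend.Z, "p_value": trend.p_value},
            "series": [float(v) for v in s],
        }
    mw = mann_whitney(series["intervention"], series["control"])
    report["mann_whitney_active_minutes"] = {
        "U": mw.statistic_U,
        "W": mw.statistic_W,
        "p_value": mw.p_value,
        "method": mw.method,
    }
    return report
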