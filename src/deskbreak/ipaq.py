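"""IPAQ short-form scoring and stratified arm allocation.

The International Physical Activity Questionnaire (IPAQ) summarizes a week
of self-reported activity into MET-minutes: for each activity class, the MET
level (walking 3.3, moderate 4.0, vigorous 8.0 — multiples of resting
metabolic rate) times minutes per day times days per week.  Totals classify
respondents as low (< 600 MET-min/week), moderate (600 to < 3,000) or high
(>= 3,000); the exact thresholds land in the higher class per the official
scoring convention.  Full short-form extras (per-item truncation, the
vigorous-days alternative route to "high") are deliberately not applied —
only the MET-minute thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

MET_WALKING = 3.3
MET_MODERATE = 4.0
MET_VIGOROUS = 8.0

LOW_CUTOFF = 600.0     # MET-min/week
HIGH_CUTOFF = 3000.0   # MET-min/week

CATEGORIES = ("low", "moderate", "high")
ARMS = ("control", "intervention")


@dataclass(frozen=True)
class IpaqReport:
    """Days/week and minutes/day for each activity class."""

    walk_days: int
    walk_min: float
    mod_days: int
    mod_min: float
    vig_days: int
    vig_min: float

    def __post_init__(self) -> None:
        for name in ("walk_days", "mod_days", "vig_days"):
            d = getattr(self, name)
            if not 0 <= d <= 7:
                raise ValueError(f"{name} must be in [0, 7], got {d}")
        for name in ("walk_min", "mod_min", "vig_min"):
            m = getattr(self, name)
            if m < 0:
                raise ValueError(f"{name} must be >= 0, got {m}")


@dataclass(frozen=True)
class IpaqScore:
    met_minutes_per_week: float
    category: str


def met_minutes(report: IpaqReport) -> float:
    """Weekly MET-minutes: sum of MET level x min/day x days/week."""
    return (
        MET_WALKING * report.walk_min * report.walk_days
        + MET_MODERATE * report.mod_min * report.mod_days
        + MET_VIGOROUS * report.vig_min * report.vig_days
    )


def classify(met_min: float) -> str:
    if met_min < 0:
        raise ValueError(f"MET-minutes must be >= 0, got {met_min}")
    if met_min < LOW_CUTOFF:
        return "low"
    if met_min < HIGH_CUTOFF:
        return "moderate"
    return "high"


def score(report: IpaqReport) -> IpaqScore:
    mm = met_minutes(report)
    return IpaqScore(met_minutes_per_week=mm, category=classify(mm))


def stratified_allocate(categories: Sequence[str], seed: int) -> list[str]:
    """Assign arms so each IPAQ category splits near-evenly between them.

    Within each category, members are shuffled (seeded) and dealt alternately
    to the two arms; the arm receiving an odd category's extra member is the
    one currently behind, so total arm sizes differ by at most 1.
    """
    if len(categories) < 2:
        raise ValueError("need at least 2 participants to allocate")
    rng = np.random.default_rng(seed)
    arms: list[str | None] = [None] * len(categories)
    totals = {"control": 0, "intervention": 0}
    for cat in sorted(set(categories)):
        idx = [i for i, c in enumerate(categories) if c == cat]
        rng.shuffle(idx)
        # start with whichever arm is behind overall to keep totals balanced
        first = "control" if totals["control"] <= totals["intervention"] else "intervention"
        second = "intervention" if first == "control" else "control"
        for k, i in enumerate(idx):
            arm = first if k % 2 == 0 else second
            arms[i] = arm
            totals[arm] += 1
    return arms  # type: ignore[return-value]
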