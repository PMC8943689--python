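"""Derived log variables: dismissal, break of inactivity, engagement tiers,
active minutes, and contingency-table construction."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from deskbreak.analytics import (
    DerivedMessageRecord,
    MessageLogRecord,
    build_break_table,
    classify_engagement,
    daily_active_minutes,
    derive_frame,
    evaluate_break,
    mark_dismissed,
    engagement_table,
)
from deskbreak.engine import EngineConfig


def record(
    view=10.0,
    explicit=False,
    before=1000,
    after=1100,
    arm="intervention",
    msg_type="context_aware",
    framing="gain_framed",
) -> MessageLogRecord:
    return MessageLogRecord(
        user_id="u001",
        arm=arm,
        sent_at=datetime(2021, 12, 5, 10, 0),
        msg_type=msg_type,
        category_id="generic-outdoor" if arm == "intervention" else None,
        framing=framing if arm == "intervention" else None,
        text="walk",
        steps_before=before,
        steps_after_30=after,
        view_seconds=view,
        explicitly_dismissed=explicit,
    )


class TestDismissal:
    @pytest.mark.parametrize(
        "view,explicit,expected",
        [
            (10.0, True, True),    # explicitly dismissed despite a long view
            (1.9, False, True),    # glanced under the 2-s rule
            (2.0, False, False),   # boundary: strictly-less-than rule
            (8.0, False, False),
        ],
    )
    def test_rule(self, cfg, view, explicit, expected):
        assert mark_dismissed(record(view=view, explicit=explicit), cfg) is expected

    def test_negative_view_time_rejected(self):
        with pytest.raises(ValueError):
            record(view=-1.0)


class TestBreakEvaluation:
    @pytest.mark.parametrize("after,expected", [(1067, True), (1066, False)])
    def test_67_step_criterion(self, cfg, after, expected):
        d = evaluate_break(record(before=1000, after=after), cfg)
        assert d.step_delta == after - 1000
        assert d.broke_inactivity is expected

    def test_dismissed_is_not_applicable(self, cfg):
        d = evaluate_break(record(view=0.5, after=1500), cfg)
        assert d.dismissed and d.broke_inactivity is None

    def test_missing_after_window_is_not_applicable(self, cfg):
        d = evaluate_break(record(after=None), cfg)
        assert d.step_delta is None and d.broke_inactivity is None

    def test_nonmonotone_counter_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            record(before=1000, after=900)

    def test_control_records_must_be_static(self):
        with pytest.raises(ValueError):
            record(arm="control", msg_type="context_aware")


class TestEngagement:
    @pytest.mark.parametrize(
        "days,weeks,tier",
        [
            (0, 0, "inactive"),
            (21, 3, "inactive"),
            (22, 4, "semiactive"),
            (42, 6, "semiactive"),
            (43, 7, "active"),
            (66, 10, "active"),
        ],
    )
    def test_week_boundaries(self, days, weeks, tier):
        rec = classify_engagement(days)
        assert (rec.weeks, rec.tier) == (weeks, tier)

    def test_monotone_in_days(self):
        order = {"inactive": 0, "semiactive": 1, "active": 2}
        tiers = [order[classify_engagement(d).tier] for d in range(0, 80)]
        assert tiers == sorted(tiers)


class TestActiveMinutes:
    def test_all_zero_trace(self):
        assert daily_active_minutes(np.zeros(1440, dtype=int)) == 0

    def test_exact_count(self):
        trace = np.zeros(1440, dtype=int)
        trace[100:130] = 100
        assert daily_active_minutes(trace) == 30

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            trace = rng.poisson(3, size=1440)
            threshold = int(rng.integers(1, 20))
            oracle = sum(1 for s in trace if s >= threshold)
            assert daily_active_minutes(trace, threshold) == oracle

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="1,440"):
            daily_active_minutes(np.zeros(100))


class TestBreakTable:
    def test_reproduces_study_shape_from_records(self, cfg):
        """Records built to match the published per-type break counts
        tabulate back to exactly those counts."""
        recs = []
        for msg_type, arm, (no_break, broke) in [
            ("context_aware", "intervention", (3, 5)),
            ("static", "control", (4, 1)),
        ]:
            for broke_flag, n in [(False, no_break), (True, broke)]:
                delta = 100 if broke_flag else 10
                recs += [
                    evaluate_break(
                        record(arm=arm, msg_type=msg_type, before=0, after=delta), cfg
                    )
                    for _ in range(n)
                ]
        tab = build_break_table(recs, "msg_type")
        assert tab.counts == ((3, 5), (4, 1))
        assert tab.row_labels == ("context_aware", "static")
        # conservation: every non-dismissed record lands in exactly one cell
        assert sum(sum(r) for r in tab.counts) == len(recs)

    def test_single_record(self, cfg):
        tab = build_break_table([evaluate_break(record(before=0, after=200), cfg)], "msg_type")
        assert tab.counts == ((0, 1),)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_break_table([], "msg_type")


class TestFramePipeline:
    def test_frame_derivation_matches_record_level(self, cfg, small_cohort):
        logs = small_cohort.logs_frame()
        logs["sent_at"] = pd.to_datetime(logs["sent_at"])
        derived = derive_frame(logs, cfg)
        sample = derived.sample(n=min(200, len(derived)), random_state=0)
        for _, row in sample.iterrows():
            rec = record(
                view=row.view_seconds,
                explicit=bool(row.explicitly_dismissed),
                before=int(row.steps_before),
                after=None if pd.isna(row.steps_after_30) else int(row.steps_after_30),
                arm=row.arm,
                msg_type=row.msg_type,
                framing=row.framing if row.arm == "intervention" else None,
            )
            d = evaluate_break(rec, cfg)
            assert bool(row.dismissed) == d.dismissed
            broke = None if pd.isna(row.broke_inactivity) else bool(row.broke_inactivity)
            assert broke == d.broke_inactivity

    def test_engagement_table_counts_match_profiles(self, small_cohort):
        profiles = small_cohort.profiles_frame()
        tab = engagement_table(profiles)
        assert sum(sum(r) for r in tab.counts) == len(profiles)
        assert tab.col_labels == ("control", "intervention")
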