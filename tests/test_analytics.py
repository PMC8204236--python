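"""Adherence, skill-utilization, and delivery metrics."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from skillnudge.analytics import (
    custom_push_session_rate,
    days_used_pct,
    entries_per_day,
    intention_rate,
    intervention_distribution,
    pct_eating_enough_by_week,
    pct_urge_skill_use_by_week,
    weekly_metrics_frame,
)
from skillnudge.clinician import Visit
from skillnudge.errors import UndefinedMetricError
from skillnudge.models import DeliveredIntervention, Skill, Trigger

from conftest import make_entry


def delivery(i, skill, trigger=Trigger.urge, intends=None, reason=None):
    return DeliveredIntervention(
        delivery_id=f"d{i}",
        patient_id="pt",
        timestamp=dt.datetime(2024, 1, 1, 12) + dt.timedelta(minutes=i),
        trigger=trigger,
        skill=skill,
        intends_to_use=intends,
        decline_reason=reason,
    )


def deliveries_with_counts(counts: dict) -> list:
    out, i = [], 0
    for skill, n in counts.items():
        for _ in range(n):
            trig = Trigger.custom_push if skill is None else Trigger.urge
            out.append(delivery(i, skill, trigger=trig))
            i += 1
    return out


class TestAdherence:
    def test_six_of_seven_days(self):
        period = (dt.date(2024, 1, 1), dt.date(2024, 1, 7))
        entries = [
            make_entry(entry_id=f"e{d}", timestamp=dt.datetime(2024, 1, d, 12))
            for d in range(1, 7)
        ]
        assert days_used_pct(entries, period) == 85.7

    def test_full_coverage_is_100(self):
        period = (dt.date(2024, 1, 1), dt.date(2024, 1, 7))
        entries = [
            make_entry(entry_id=f"e{d}", timestamp=dt.datetime(2024, 1, d, 12))
            for d in range(1, 8)
        ]
        assert days_used_pct(entries, period) == 100.0

    def test_pooled_470_of_539_days(self):
        # one long enrollment period with 470 distinct active days
        start = dt.date(2023, 1, 1)
        period = (start, start + dt.timedelta(days=538))
        entries = [
            make_entry(
                entry_id=f"e{i}",
                timestamp=dt.datetime.combine(
                    start + dt.timedelta(days=i), dt.time(12)
                ),
            )
            for i in range(470)
        ]
        assert days_used_pct(entries, period) == 87.2

    def test_entries_per_day(self):
        period = (dt.date(2024, 1, 1), dt.date(2024, 1, 7))
        entries = [
            make_entry(
                entry_id=f"e{i}",
                timestamp=dt.datetime(2024, 1, 1 + i % 7, 8) + dt.timedelta(minutes=i),
            )
            for i in range(21)
        ]
        assert entries_per_day(entries, period) == pytest.approx(3.0)
        assert entries_per_day([], period) == 0.0

    def test_empty_period_undefined(self):
        with pytest.raises(UndefinedMetricError):
            days_used_pct([], (dt.date(2024, 1, 2), dt.date(2024, 1, 1)))


class TestWeeklySeries:
    def _two_week_fixture(self):
        """Hand-built: wk1 10 eligible episodes 7 'enough', 4 urges 3 managed;
        wk2 includes a LOC episode that endorses ate_enough (must be excluded)."""
        entries = []
        day0 = dt.datetime(2024, 1, 1, 12)
        for i in range(10):
            entries.append(
                make_entry(
                    entry_id=f"w1e{i}",
                    timestamp=day0 + dt.timedelta(hours=i * 8),
                    ate_enough=i < 7,
                    ate_macro_range=False,
                )
            )
        from skillnudge.models import EntryKind

        for i in range(4):
            entries.append(
                make_entry(
                    entry_id=f"w1u{i}",
                    entry_kind=EntryKind.other,  # urge-only records, not episodes
                    timestamp=day0 + dt.timedelta(hours=2 + i * 20),
                    urge_present=True,
                    used_urge_strategy=i < 3,
                )
            )
        # week 2: 2 plain eligible episodes (1 hit) + 1 LOC binge claiming ate_enough
        wk2 = day0 + dt.timedelta(days=7)
        entries.append(make_entry(entry_id="w2a", timestamp=wk2, ate_enough=True))
        entries.append(make_entry(entry_id="w2b", timestamp=wk2 + dt.timedelta(hours=5)))
        entries.append(
            make_entry(
                entry_id="w2loc",
                timestamp=wk2 + dt.timedelta(hours=9),
                loss_of_control=True,
                behaviors=frozenset({"binge"}),
                ate_enough=True,
            )
        )
        return entries

    def test_eating_enough_series_matches_hand_arithmetic(self):
        series = pct_eating_enough_by_week(self._two_week_fixture())
        assert series.loc[1] == 70.0
        assert series.loc[2] == 50.0  # LOC episode excluded from both sides

    def test_urge_series_matches_hand_arithmetic(self):
        series = pct_urge_skill_use_by_week(self._two_week_fixture())
        assert series.loc[1] == 75.0
        assert np.isnan(series.loc[2])  # no urges in week 2

    def test_all_true_week_is_100(self):
        entries = [
            make_entry(entry_id=f"e{i}", timestamp=dt.datetime(2024, 1, 1 + i, 12),
                       ate_enough=True)
            for i in range(5)
        ]
        assert pct_eating_enough_by_week(entries).loc[1] == 100.0

    def test_series_invariant_to_record_order(self):
        entries = self._two_week_fixture()
        shuffled = list(reversed(entries))
        pd.testing.assert_series_equal(
            pct_eating_enough_by_week(entries), pct_eating_enough_by_week(shuffled)
        )
        pd.testing.assert_series_equal(
            pct_urge_skill_use_by_week(entries), pct_urge_skill_use_by_week(shuffled)
        )

    def test_weekly_frame_covers_both_weeks(self):
        frame = weekly_metrics_frame(self._two_week_fixture())
        assert list(frame.index) == [1, 2]
        assert frame.loc[1, "entries"] == 14


class TestDeliveryMetrics:
    def test_restraint_and_cue_shares_from_pilot_counts(self):
        counts = {
            Skill.REGULAR_EATING: 1288,
            Skill.EAT_ENOUGH: 152,
            Skill.FEARED_FOODS: 21,
            Skill.URGE_MANAGEMENT: 48,
            Skill.TRIGGER_AWARENESS: 9,
            Skill.MOOD_MANAGEMENT: 8,
            None: 64,
        }
        dist = intervention_distribution(deliveries_with_counts(counts))
        assert dist.total == 1590
        assert dist.restraint_pct == 91.89
        assert dist.cues_pct == 4.09
        assert dist.per_skill_pct[Skill.REGULAR_EATING] == 81.01

    def test_single_skill_is_100_pct(self):
        dist = intervention_distribution(
            deliveries_with_counts({Skill.URGE_MANAGEMENT: 7})
        )
        assert dist.per_skill_pct[Skill.URGE_MANAGEMENT] == 100.0
        assert dist.cues_pct == 100.0

    def test_shares_sum_to_total_within_rounding(self):
        dist = intervention_distribution(
            deliveries_with_counts(
                {Skill.REGULAR_EATING: 3, Skill.URGE_MANAGEMENT: 2, Skill.EAT_ENOUGH: 2}
            )
        )
        assert sum(dist.per_skill_pct.values()) == pytest.approx(100.0, abs=0.05)

    def test_zero_deliveries_undefined(self):
        with pytest.raises(UndefinedMetricError):
            intervention_distribution([])

    def test_intention_rate_372_of_383(self):
        ds = [
            delivery(i, Skill.URGE_MANAGEMENT, intends=True) for i in range(372)
        ] + [
            delivery(400 + i, Skill.URGE_MANAGEMENT, intends=False, reason="too_hard")
            for i in range(11)
        ]
        assert intention_rate(ds) == 97.1

    @pytest.mark.parametrize(
        "n_yes,n_no,expected", [(5, 0, 100.0), (0, 5, 0.0)]
    )
    def test_intention_rate_extremes(self, n_yes, n_no, expected):
        ds = [delivery(i, None, trigger=Trigger.custom_push, intends=True) for i in range(n_yes)]
        ds += [
            delivery(100 + i, None, trigger=Trigger.custom_push, intends=False, reason="not_relevant")
            for i in range(n_no)
        ]
        assert intention_rate(ds) == expected

    def test_unanswered_deliveries_excluded(self):
        ds = [delivery(0, Skill.URGE_MANAGEMENT, intends=True), delivery(1, Skill.URGE_MANAGEMENT)]
        assert intention_rate(ds) == 100.0


class TestCustomPushRate:
    def _visits(self, with_push: int, total: int):
        from skillnudge.scheduler import PushSchedule

        visits = []
        for i in range(total):
            v = Visit(f"v{i}", dt.date(2024, 1, 1) + dt.timedelta(days=7 * i))
            if i < with_push:
                v.created_pushes.append(
                    PushSchedule(push_id=f"p{i}", message="m", when=dt.datetime(2024, 6, 1, 12))
                )
            visits.append(v)
        return visits

    def test_9_of_56_rounds_to_16(self):
        assert custom_push_session_rate(self._visits(9, 56)) == 16

    @pytest.mark.parametrize("with_push,total,expected", [(0, 10, 0), (7, 7, 100)])
    def test_extremes(self, with_push, total, expected):
        assert custom_push_session_rate(self._visits(with_push, total)) == expected
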