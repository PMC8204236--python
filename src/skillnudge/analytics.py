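"""Log-derived adherence, skill-utilization, and delivery metrics.

Adherence is quantified as the percentage of enrollment days with at least one
entry and the mean number of entries per day, with the analysis period
truncated at dropout. Skill utilization is tracked weekly: the share of
regular (non-loss-of-control) eating episodes where the patient endorsed
eating enough and/or eating a range of macronutrients, and the share of
urge-relevant records where an urge management strategy was used. Delivery
metrics cover the per-skill distribution of interventions (with restraint vs
cue-response aggregates), the intend-to-use rate, and how often clinicians
created custom pushes during visits.

Treatment weeks are 7-day bins anchored at the date of the earliest entry, so
all metrics are invariant to record order. Rates carry 1 decimal, distribution
shares 2 decimals.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .clinician import Visit
from .errors import UndefinedMetricError
from .models import (
    CUE_SKILLS,
    RESTRAINT_SKILLS,
    SKILL_PRECEDENCE,
    DeliveredIntervention,
    EntryRecord,
    Skill,
)

Period = tuple[dt.date, dt.date]

__all__ = [
    "days_used_pct",
    "entries_per_day",
    "treatment_week",
    "pct_eating_enough_by_week",
    "pct_urge_skill_use_by_week",
    "InterventionDistribution",
    "intervention_distribution",
    "intention_rate",
    "custom_push_session_rate",
    "weekly_metrics_frame",
]


def _n_days(period: Period) -> int:
    start, end = period
    n = (end - start).days + 1
    if n <= 0:
        raise UndefinedMetricError("analysis period is empty")
    return n


def days_used_pct(entries: Iterable[EntryRecord], period: Period) -> float:
    """Percent of period days (inclusive) with >= 1 entry, 1 decimal."""
    n = _n_days(period)
    start, end = period
    used = {e.timestamp.date() for e in entries if start <= e.timestamp.date() <= end}
    return round(100.0 * len(used) / n, 1)


def entries_per_day(entries: Iterable[EntryRecord], period: Period) -> float:
    """Mean entries per day over the period (dropout-truncated enrollment)."""
    n = _n_days(period)
    start, end = period
    count = sum(1 for e in entries if start <= e.timestamp.date() <= end)
    return count / n


def treatment_week(day: dt.date, anchor: dt.date) -> int:
    """1-based 7-day treatment week containing ``day``, anchored at ``anchor``."""
    return (day - anchor).days // 7 + 1


def _anchor(entries: Sequence[EntryRecord]) -> dt.date:
    return min(e.timestamp.date() for e in entries)


def _weekly_ratio(
    entries: Sequence[EntryRecord],
    is_eligible,
    is_hit,
    anchor: Optional[dt.date],
) -> pd.Series:
    if not entries:
        return pd.Series(dtype=float, name="pct")
    anchor = anchor if anchor is not None else _anchor(entries)
    eligible: dict[int, int] = {}
    hits: dict[int, int] = {}
    last_week = 1
    for e in entries:
        week = treatment_week(e.timestamp.date(), anchor)
        last_week = max(last_week, week)
        if is_eligible(e):
            eligible[week] = eligible.get(week, 0) + 1
            if is_hit(e):
                hits[week] = hits.get(week, 0) + 1
    index = pd.RangeIndex(1, last_week + 1, name="week")
    values = [
        round(100.0 * hits.get(w, 0) / eligible[w], 1) if eligible.get(w) else np.nan
        for w in index
    ]
    return pd.Series(values, index=index, name="pct")


def pct_eating_enough_by_week(
    entries: Sequence[EntryRecord], anchor: Optional[dt.date] = None
) -> pd.Series:
    """Weekly % of regular eating episodes where the patient ate enough.

    Eligible episodes are eating episodes WITHOUT loss of control; an episode
    counts if either "ate enough to prevent excessive hunger" or "ate a range
    of macronutrients" was endorsed. Weeks without eligible episodes are NaN.
    """
    return _weekly_ratio(
        entries,
        is_eligible=lambda e: e.is_eating_episode and not e.loss_of_control,
        is_hit=lambda e: bool(e.ate_enough) or bool(e.ate_macro_range),
        anchor=anchor,
    )


def pct_urge_skill_use_by_week(
    entries: Sequence[EntryRecord], anchor: Optional[dt.date] = None
) -> pd.Series:
    """Weekly % of urge-relevant records with an urge management strategy used.

    Relevant records are those reporting an urge; weeks with no urges are NaN.
    """
    return _weekly_ratio(
        entries,
        is_eligible=lambda e: e.urge_present,
        is_hit=lambda e: bool(e.used_urge_strategy),
        anchor=anchor,
    )


@dataclass(frozen=True)
class InterventionDistribution:
    """Per-skill shares of all deliveries, plus restraint/cue aggregates (%)."""

    total: int
    per_skill_pct: dict[Skill, float]
    restraint_pct: float
    cues_pct: float


def intervention_distribution(
    deliveries: Sequence[DeliveredIntervention],
) -> InterventionDistribution:
    """Distribution of deliveries over skills, percentages to 2 decimals.

    Skill-less deliveries (e.g. custom motivational pushes) count toward the
    total but toward neither the restraint nor the cue-response aggregate.
    """
    total = len(deliveries)
    if total == 0:
        raise UndefinedMetricError("no deliveries: distribution undefined")
    counts: dict[Skill, int] = {s: 0 for s in SKILL_PRECEDENCE}
    for d in deliveries:
        if d.skill is not None:
            counts[d.skill] += 1
    pct = {s: round(100.0 * c / total, 2) for s, c in counts.items()}
    restraint = sum(counts[s] for s in RESTRAINT_SKILLS)
    cues = sum(counts[s] for s in CUE_SKILLS)
    return InterventionDistribution(
        total=total,
        per_skill_pct=pct,
        restraint_pct=round(100.0 * restraint / total, 2),
        cues_pct=round(100.0 * cues / total, 2),
    )


def intention_rate(deliveries: Sequence[DeliveredIntervention]) -> float:
    """Percent of responded deliveries with intends_to_use=True, 1 decimal."""
    responded = [d for d in deliveries if d.intends_to_use is not None]
    if not responded:
        raise UndefinedMetricError("no responded deliveries: rate undefined")
    return round(
        100.0 * sum(d.intends_to_use for d in responded) / len(responded), 1
    )


def custom_push_session_rate(visits: Sequence[Visit]) -> int:
    """Percent of visits in which >= 1 custom push was created, nearest integer."""
    if not visits:
        raise UndefinedMetricError("no visits: rate undefined")
    with_push = sum(1 for v in visits if v.created_pushes)
    return int(round(100.0 * with_push / len(visits)))


def weekly_metrics_frame(
    entries: Sequence[EntryRecord],
    deliveries: Sequence[DeliveredIntervention] = (),
    anchor: Optional[dt.date] = None,
) -> pd.DataFrame:
    """Tidy per-week metric table (one row per patient-week).

    Columns: entries, entries_per_day, days_used_pct, deliveries,
    pct_eating_enough, pct_urge_skill_use.
    """
    if not entries:
        return pd.DataFrame(
            columns=[
                "entries",
                "entries_per_day",
                "days_used_pct",
                "deliveries",
                "pct_eating_enough",
                "pct_urge_skill_use",
            ]
        )
    anchor = anchor if anchor is not None else _anchor(entries)
    enough = pct_eating_enough_by_week(entries, anchor=anchor)
    urge = pct_urge_skill_use_by_week(entries, anchor=anchor)
    weeks = enough.index
    rows = []
    for w in weeks:
        w_start = anchor + dt.timedelta(days=7 * (w - 1))
        w_end = w_start + dt.timedelta(days=6)
        in_week = [e for e in entries if w_start <= e.timestamp.date() <= w_end]
        dl_week = [d for d in deliveries if w_start <= d.timestamp.date() <= w_end]
        rows.append(
            {
                "week": w,
                "entries": len(in_week),
                "entries_per_day": len(in_week) / 7.0,
                "days_used_pct": days_used_pct(in_week, (w_start, w_end)),
                "deliveries": len(dl_week),
                "pct_eating_enough": enough.loc[w],
                "pct_urge_skill_use": urge.loc[w],
            }
        )
    return pd.DataFrame(rows).set_index("week")
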