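"""Clinician portal workflow: skills, visits, goals, dashboard, calendar.

The clinician controls the momentary algorithm entirely through configuration:
opening skills as they are introduced in session, setting up to three priority
goals per visit (each linked to intervention content), and optionally creating
custom push notifications. Closing a visit snapshots the goal set into the
patient's goals timeline, which is what the engine consults at run time.

The dashboard and calendar views are the audit surface: weekly counts of
entries, binge episodes (loss-of-control eating with a binge flag),
compensatory behaviors, deliveries and intend-to-use rate, plus a per-day
red-flag map of endorsed behaviors. Compensatory behaviors are flagged on the
calendar alongside binges, and a day is never flagged without an explicitly
endorsed behavior — ordinary eating episodes cannot be mistaken for binges.
"""

from __future__ import annotations

import calendar as _calendar
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import (
    ConfigurationError,
    DependencyError,
    LimitError,
)
from .models import (
    Behavior,
    COMPENSATORY_BEHAVIORS,
    DeliveredIntervention,
    EntryRecord,
    GoalSegment,
    GoalsTimeline,
    InterventionTemplate,
    PatientConfig,
    PriorityGoal,
    Skill,
)
from .scheduler import PushSchedule, validate_custom_push

__all__ = [
    "Visit",
    "open_skill",
    "set_visit_goals",
    "close_visit",
    "create_custom_push",
    "DashboardSummary",
    "dashboard_summary",
    "calendar_flags",
]


@dataclass
class Visit:
    """One in-person session's configuration actions."""

    visit_id: str
    date: dt.date
    goals: list[PriorityGoal] = field(default_factory=list)
    custom_templates: list[InterventionTemplate] = field(default_factory=list)
    created_pushes: list[PushSchedule] = field(default_factory=list)
    notes: str = ""
    closed: bool = False


def open_skill(config: PatientConfig, skill: Skill) -> PatientConfig:
    """Open a skill once it has been introduced in therapy (idempotent).

    Only opened skills can back priority goals or appear in the on-demand
    repository.
    """
    if skill in config.opened_skills:
        return config
    return config.model_copy(update={"opened_skills": set(config.opened_skills) | {skill}})


def set_visit_goals(
    visit: Visit, goals: Sequence[PriorityGoal], config: PatientConfig
) -> Visit:
    """Attach 1-3 priority goals to a visit.

    Each skill-linked goal requires its skill to be opened first; more than 3
    goals raise :class:`~skillnudge.errors.LimitError`.
    """
    if not goals:
        raise ConfigurationError("a visit must set at least one priority goal")
    if len(goals) > 3:
        raise LimitError(f"at most 3 priority goals per visit, got {len(goals)}")
    for goal in goals:
        if goal.skill is not None and goal.skill not in config.opened_skills:
            raise DependencyError(
                f"goal {goal.goal_id!r} targets unopened skill {goal.skill.value}"
            )
    visit.goals = [
        g.model_copy(update={"active_from": visit.date}) for g in goals
    ]
    return visit


def close_visit(
    visit: Visit,
    config: PatientConfig,
    timeline: Optional[GoalsTimeline] = None,
    templates: Optional[dict[str, InterventionTemplate]] = None,
) -> tuple[PatientConfig, GoalsTimeline]:
    """Save-and-close a visit, updating the patient's algorithm configuration.

    Registers any inline custom templates, verifies every goal is linked to at
    least one known template, closes the previous goal segment at the visit
    date, appends the new segment (open-ended until the next visit), and sets
    the goal priority order to the listed order.
    """
    if visit.closed:
        raise ConfigurationError(f"visit {visit.visit_id!r} is already closed")
    if not visit.goals:
        raise ConfigurationError("cannot close a visit with no goals set")
    timeline = timeline if timeline is not None else GoalsTimeline()
    templates = templates if templates is not None else {}
    for tpl in visit.custom_templates:
        templates[tpl.template_id] = tpl
    for goal in visit.goals:
        if not goal.linked_template_ids:
            raise ConfigurationError(
                f"goal {goal.goal_id!r} has no linked interventions"
            )
        missing = [t for t in goal.linked_template_ids if t not in templates]
        if missing:
            raise ConfigurationError(
                f"goal {goal.goal_id!r} links unknown templates {missing}"
            )

    segments = list(timeline.segments)
    if segments and segments[-1].end is None:
        prev = segments[-1]
        if prev.start >= visit.date:
            raise ConfigurationError("visit date must follow the previous visit")
        segments[-1] = prev.model_copy(update={"end": visit.date})
    new_timeline = GoalsTimeline(
        segments=tuple(segments)
        + (GoalSegment(start=visit.date, goals=tuple(visit.goals)),)
    )
    new_config = config.model_copy(
        update={"goal_priority_order": tuple(g.goal_id for g in visit.goals)}
    )
    visit.closed = True
    return new_config, new_timeline


def create_custom_push(
    visit: Visit, push: PushSchedule, config: PatientConfig
) -> PushSchedule:
    """Record a clinician custom push created during a visit (window-checked)."""
    validate_custom_push(push, config)
    visit.created_pushes.append(push)
    return push


@dataclass(frozen=True)
class DashboardSummary:
    """Weekly at-a-glance counts for the patient dashboard."""

    n_entries: int
    n_binge_episodes: int
    n_compensatory_behaviors: int
    n_deliveries: int
    intend_to_use_pct: Optional[float]


def _is_binge_episode(entry: EntryRecord) -> bool:
    return entry.loss_of_control and Behavior.binge in entry.behaviors


def dashboard_summary(
    entries: Iterable[EntryRecord],
    deliveries: Iterable[DeliveredIntervention],
    week: tuple[dt.date, dt.date],
) -> DashboardSummary:
    """Summarize one week (inclusive date range) of patient data."""
    start, end = week
    in_week = [e for e in entries if start <= e.timestamp.date() <= end]
    dl_week = [d for d in deliveries if start <= d.timestamp.date() <= end]
    responded = [d for d in dl_week if d.intends_to_use is not None]
    rate = (
        round(100.0 * sum(d.intends_to_use for d in responded) / len(responded), 1)
        if responded
        else None
    )
    return DashboardSummary(
        n_entries=len(in_week),
        n_binge_episodes=sum(_is_binge_episode(e) for e in in_week),
        n_compensatory_behaviors=sum(
            len(e.behaviors & COMPENSATORY_BEHAVIORS) for e in in_week
        ),
        n_deliveries=len(dl_week),
        intend_to_use_pct=rate,
    )


def calendar_flags(
    entries: Iterable[EntryRecord], year: int, month: int
) -> dict[dt.date, frozenset[Behavior]]:
    """Red-flag map for one calendar month: date -> endorsed behavior kinds.

    Binges and compensatory behaviors are both flagged. A binge flag requires
    an explicitly endorsed binge behavior — never inferred from an ordinary
    eating episode.
    """
    _, n_days = _calendar.monthrange(year, month)
    flags: dict[dt.date, set[Behavior]] = {
        dt.date(year, month, d): set() for d in range(1, n_days + 1)
    }
    for entry in entries:
        day = entry.timestamp.date()
        if day in flags:
            flags[day] |= entry.behaviors
    return {day: frozenset(v) for day, v in flags.items()}
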