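"""Waking-hours arithmetic and push-notification scheduling.

The decision rules reason in *waking* time: only the portion of the clock that
falls inside the patient's daily waking window (default 08:00-23:00) counts
toward gaps. :func:`waking_hours_between` measures elapsed waking time,
:func:`next_monitoring_reminder` places the "please enter data" reminder after
a configurable waking-hours silence, and :func:`due_pushes` expands clinician
custom push schedules (one-time or days-of-week recurrences) over a date range.
"""

from __future__ import annotations

import datetime as dt
import enum
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigurationError, OrderingError
from .models import EngineState, PatientConfig, Skill

Window = tuple[dt.time, dt.time]

__all__ = [
    "PushKind",
    "Recurrence",
    "PushSchedule",
    "waking_hours_between",
    "advance_waking",
    "next_monitoring_reminder",
    "due_pushes",
    "validate_custom_push",
]


class PushKind(str, enum.Enum):
    self_monitoring_reminder = "self_monitoring_reminder"
    custom = "custom"


class Recurrence(BaseModel):
    """Days-of-week + clock-time recurrence between two dates (inclusive).

    Deliberately not cron-general: clinician custom pushes in practice are
    patterns like "Friday 16:00 before happy hour" or "weekday evenings".
    Weekdays are 0=Monday .. 6=Sunday.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    days_of_week: frozenset[int]
    at: dt.time
    start_date: dt.date
    end_date: dt.date

    @model_validator(mode="after")
    def _check(self) -> "Recurrence":
        if not self.days_of_week or not all(0 <= d <= 6 for d in self.days_of_week):
            raise ConfigurationError("days_of_week must be a nonempty subset of 0..6")
        if self.end_date < self.start_date:
            raise ConfigurationError("recurrence end_date must be >= start_date")
        return self


class PushSchedule(BaseModel):
    """A scheduled push notification, one-time (datetime) or recurring."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    push_id: str
    kind: PushKind = PushKind.custom
    message: str = ""
    skill: Optional[Skill] = None
    when: Union[dt.datetime, Recurrence]
    active: bool = True


def validate_custom_push(schedule: PushSchedule, config: PatientConfig) -> None:
    """Reject a custom push whose clock time falls outside the waking window."""
    start, end = config.waking_window
    t = schedule.when.at if isinstance(schedule.when, Recurrence) else schedule.when.time()
    if not (start <= t < end):
        raise ConfigurationError(
            f"push time {t.isoformat()} is outside waking window "
            f"{start.isoformat()}-{end.isoformat()}"
        )


def waking_hours_between(t1: dt.datetime, t2: dt.datetime, window: Window) -> float:
    """Waking time elapsed between two datetimes, in hours.

    The measure is the Lebesgue length of [t1, t2] intersected with the daily
    waking window, so it is additive over concatenated intervals and never
    negative. Raises :class:`~skillnudge.errors.OrderingError` if ``t1 > t2``.
    """
    if t1 > t2:
        raise OrderingError(f"interval start {t1} is after end {t2}")
    start, end = window
    total = 0.0
    day = t1.date()
    while day <= t2.date():
        lo = max(t1, dt.datetime.combine(day, start))
        hi = min(t2, dt.datetime.combine(day, end))
        if hi > lo:
            total += (hi - lo).total_seconds() / 3600.0
        day += dt.timedelta(days=1)
    return total


def advance_waking(t0: dt.datetime, hours: float, window: Window) -> dt.datetime:
    """Earliest time ``t >= t0`` with ``waking_hours_between(t0, t) >= hours``.

    The result always lies inside the waking window (window-end landings roll
    over to the next morning's window start).
    """
    start, end = window
    cur = t0
    if cur.time() < start:
        cur = dt.datetime.combine(cur.date(), start)
    elif cur.time() >= end:
        cur = dt.datetime.combine(cur.date() + dt.timedelta(days=1), start)
    remaining = hours
    while True:
        available = (
            dt.datetime.combine(cur.date(), end) - cur
        ).total_seconds() / 3600.0
        if remaining < available:
            return cur + dt.timedelta(hours=remaining)
        remaining -= available
        cur = dt.datetime.combine(cur.date() + dt.timedelta(days=1), start)


def next_monitoring_reminder(
    state: EngineState, config: PatientConfig, now: dt.datetime
) -> Optional[dt.datetime]:
    """When the self-monitoring reminder push is due, given the last entry.

    Returns the earliest in-window time ``t >= now`` at which
    ``monitoring_reminder_gap_h`` waking hours will have passed since the last
    entry. A new entry cancels the pending reminder and restarts the clock
    (callers simply recompute). Returns None when no entry has been made yet.
    """
    last = state.last_entry_time
    if last is None:
        return None
    if last > now:
        raise OrderingError("last entry is in the future relative to now")
    due = advance_waking(last, config.monitoring_reminder_gap_h, config.waking_window)
    if due < now:
        due = now
        start, end = config.waking_window
        if due.time() < start:
            due = dt.datetime.combine(due.date(), start)
        elif due.time() >= end:
            due = dt.datetime.combine(due.date() + dt.timedelta(days=1), start)
    return due


def due_pushes(
    schedules: list[PushSchedule], from_: dt.datetime, to: dt.datetime
) -> list[tuple[dt.datetime, PushSchedule]]:
    """All occurrences of active schedules in ``[from_, to)``, time-sorted.

    Recurring specs are expanded day by day; exact duplicate occurrences are
    emitted once.
    """
    if from_ > to:
        raise OrderingError("range start is after range end")
    out: list[tuple[dt.datetime, PushSchedule]] = []
    seen: set[tuple[dt.datetime, str]] = set()
    for sched in schedules:
        if not sched.active:
            continue
        if isinstance(sched.when, dt.datetime):
            occurrences = [sched.when]
        else:
            rec = sched.when
            occurrences = []
            day = max(rec.start_date, from_.date())
            last_day = min(rec.end_date, to.date())
            while day <= last_day:
                if day.weekday() in rec.days_of_week:
                    occurrences.append(dt.datetime.combine(day, rec.at))
                day += dt.timedelta(days=1)
        for occ in occurrences:
            if from_ <= occ < to and (occ, sched.push_id) not in seen:
                seen.add((occ, sched.push_id))
                out.append((occ, sched))
    out.sort(key=lambda pair: (pair[0], pair[1].push_id))
    return out
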