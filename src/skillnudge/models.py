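"""Domain types for the self-monitoring JITAI engine.

The engine's only sensing channel is the patient's electronic self-monitoring
log: one :class:`EntryRecord` per meal, snack, or *other* event (a disordered
eating behavior, a strong urge, or a notable mood change outside of a planned
eating episode). Clinician-side configuration lives in :class:`PatientConfig`,
weekly treatment targets in :class:`PriorityGoal`, and intervention content in
:class:`InterventionTemplate`. Every delivered momentary intervention is an
immutable :class:`DeliveredIntervention` audit record.

All timestamps are naive local datetimes: the decision rules reason in the
patient's own waking time, and a single timezone per patient is assumed.
"""

from __future__ import annotations

import datetime as dt
import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import pydantic
from pydantic import BaseModel, ConfigDict, field_serializer, model_validator

from .errors import (
    ConfigurationError,
    ConsistencyError,
    LimitError,
    RangeError,
    SchemaError,
)

__all__ = [
    "Skill",
    "RESTRAINT_SKILLS",
    "CUE_SKILLS",
    "SKILL_PRECEDENCE",
    "SKILL_INFO",
    "EntryKind",
    "MEAL_KINDS",
    "Behavior",
    "COMPENSATORY_BEHAVIORS",
    "Trigger",
    "TRIGGER_FOR_SKILL",
    "DeclineReason",
    "Barrier",
    "EntryRecord",
    "validate_entry",
    "PriorityGoal",
    "InterventionTemplate",
    "DeliveredIntervention",
    "PatientConfig",
    "EngineState",
    "TriggerCandidate",
    "GoalSegment",
    "GoalsTimeline",
]


class Skill(str, enum.Enum):
    """The six core CBT-for-BN skills the system can intervene on.

    The first three target dietary restraint (the best-established maintaining
    mechanism of binge eating); the last three target adaptive responses to
    internal and external binge cues.
    """

    REGULAR_EATING = "REGULAR_EATING"
    EAT_ENOUGH = "EAT_ENOUGH"
    FEARED_FOODS = "FEARED_FOODS"
    URGE_MANAGEMENT = "URGE_MANAGEMENT"
    TRIGGER_AWARENESS = "TRIGGER_AWARENESS"
    MOOD_MANAGEMENT = "MOOD_MANAGEMENT"


RESTRAINT_SKILLS = frozenset(
    {Skill.REGULAR_EATING, Skill.EAT_ENOUGH, Skill.FEARED_FOODS}
)
CUE_SKILLS = frozenset(
    {Skill.URGE_MANAGEMENT, Skill.TRIGGER_AWARENESS, Skill.MOOD_MANAGEMENT}
)

#: Fixed tie-breaking precedence used by the selector: restraint skills first.
SKILL_PRECEDENCE: tuple[Skill, ...] = (
    Skill.REGULAR_EATING,
    Skill.EAT_ENOUGH,
    Skill.FEARED_FOODS,
    Skill.URGE_MANAGEMENT,
    Skill.MOOD_MANAGEMENT,
    Skill.TRIGGER_AWARENESS,
)

#: Display name and on-demand repository description for each skill.
SKILL_INFO: dict[Skill, tuple[str, str]] = {
    Skill.REGULAR_EATING: (
        "Eat regular meals and snacks",
        "Schedule eating episodes at regular intervals: 3 meals and 1-2 snacks "
        "per day, with no more than a few waking hours between them.",
    ),
    Skill.EAT_ENOUGH: (
        "Eat enough food at each meal and snack",
        "Eat a sufficient amount at each episode to prevent acute hunger before "
        "the next planned eating episode, including a range of macronutrients.",
    ),
    Skill.FEARED_FOODS: (
        "Incorporate feared foods and binge-trigger foods",
        "Deliberately include avoided foods to reduce deprivation and weaken "
        "rigid food rules.",
    ),
    Skill.URGE_MANAGEMENT: (
        "Use urge management strategies to cope with urges",
        "Ride out urges to binge or compensate using distraction, urge surfing, "
        "and delay strategies instead of acting on them.",
    ),
    Skill.TRIGGER_AWARENESS: (
        "Learn your triggers for binge eating",
        "Recognize internal triggers (negative affect, urges) and external "
        "triggers (e.g. presence of palatable foods) before they lead to a binge.",
    ),
    Skill.MOOD_MANAGEMENT: (
        "Learn to manage negative emotions",
        "Modulate low mood with alternative activities and distress-tolerance "
        "strategies rather than with eating-disordered behavior.",
    ),
}


class EntryKind(str, enum.Enum):
    breakfast = "breakfast"
    midmorning_snack = "midmorning_snack"
    lunch = "lunch"
    midafternoon_snack = "midafternoon_snack"
    dinner = "dinner"
    evening_snack = "evening_snack"
    other = "other"


MEAL_KINDS = frozenset(k for k in EntryKind if k is not EntryKind.other)


class Behavior(str, enum.Enum):
    binge = "binge"
    vomiting = "vomiting"
    laxative_use = "laxative_use"
    diuretic_use = "diuretic_use"
    excessive_exercise = "excessive_exercise"
    fasting = "fasting"


COMPENSATORY_BEHAVIORS = frozenset(
    {
        Behavior.vomiting,
        Behavior.laxative_use,
        Behavior.diuretic_use,
        Behavior.excessive_exercise,
        Behavior.fasting,
    }
)


class Trigger(str, enum.Enum):
    regular_eating_gap = "regular_eating_gap"
    eat_enough = "eat_enough"
    feared_food = "feared_food"
    urge = "urge"
    mood = "mood"
    trigger_awareness = "trigger_awareness"
    custom_push = "custom_push"


TRIGGER_FOR_SKILL: dict[Skill, Trigger] = {
    Skill.REGULAR_EATING: Trigger.regular_eating_gap,
    Skill.EAT_ENOUGH: Trigger.eat_enough,
    Skill.FEARED_FOODS: Trigger.feared_food,
    Skill.URGE_MANAGEMENT: Trigger.urge,
    Skill.MOOD_MANAGEMENT: Trigger.mood,
    Skill.TRIGGER_AWARENESS: Trigger.trigger_awareness,
}


class DeclineReason(str, enum.Enum):
    not_relevant = "not_relevant"
    too_hard = "too_hard"
    other_reason = "other_reason"


class Barrier(str, enum.Enum):
    """Common barriers to skill implementation that prewritten content addresses."""

    low_accountability = "low_accountability"
    poor_awareness = "poor_awareness"
    maladaptive_habit = "maladaptive_habit"
    distress_intolerance = "distress_intolerance"
    poor_problem_solving = "poor_problem_solving"
    low_motivation = "low_motivation"
    poor_memory = "poor_memory"


def _sorted_enum_list(values) -> list[str]:
    return sorted(v.value for v in values)


class EntryRecord(BaseModel):
    """One timestamped self-monitoring entry.

    Meal/snack entries are always eating episodes; an ``other`` entry is an
    eating episode only if food was actually consumed, and must record at least
    one of a behavior, an urge, or a mood rating (that is what *other* entries
    exist for). ``ate_enough`` / ``ate_macro_range`` are the two post-meal
    check questions and only make sense on eating episodes; ``mood`` runs 1
    (good) to 5 (bad).

    ``included_feared_food`` is an optional, clinician-enabled question; when
    answered "no" on an eating episode it is the momentary practice cue for the
    feared-foods skill.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    entry_id: str
    patient_id: str
    timestamp: dt.datetime
    entry_kind: EntryKind
    foods: tuple[str, ...] = ()
    is_eating_episode: Optional[bool] = None
    loss_of_control: bool = False
    behaviors: frozenset[Behavior] = frozenset()
    urge_present: bool = False
    urge_target: Optional[Behavior] = None
    mood: Optional[int] = None
    used_mood_strategy: Optional[bool] = None
    used_urge_strategy: Optional[bool] = None
    ate_enough: Optional[bool] = None
    ate_macro_range: Optional[bool] = None
    included_feared_food: Optional[bool] = None
    comment: str = ""

    @field_serializer("behaviors")
    def _ser_behaviors(self, v: frozenset[Behavior]) -> list[str]:
        return _sorted_enum_list(v)

    @model_validator(mode="after")
    def _check(self) -> "EntryRecord":
        if self.mood is not None and not (1 <= self.mood <= 5):
            raise RangeError(f"mood must be in 1..5, got {self.mood}")
        if self.entry_kind in MEAL_KINDS:
            if self.mood is None:
                raise SchemaError(
                    f"missing field 'mood' on {self.entry_kind.value} entry"
                )
            if self.is_eating_episode is None:
                object.__setattr__(self, "is_eating_episode", True)
            elif self.is_eating_episode is False:
                raise ConsistencyError(
                    "meal/snack entries are eating episodes by definition"
                )
        else:
            if self.is_eating_episode is None:
                object.__setattr__(self, "is_eating_episode", False)
            if not (self.behaviors or self.urge_present or self.mood is not None):
                raise ConsistencyError(
                    "an 'other' entry must record a behavior, an urge, or a mood"
                )
        if not self.is_eating_episode:
            for f in ("ate_enough", "ate_macro_range", "included_feared_food"):
                if getattr(self, f) is not None:
                    raise ConsistencyError(
                        f"{f} is only asked on eating episodes"
                    )
        if self.urge_target is not None and not self.urge_present:
            raise ConsistencyError("urge_target requires urge_present")
        return self


def validate_entry(raw: Mapping[str, Any]) -> EntryRecord:
    """Validate one raw (JSON-decoded) record into an :class:`EntryRecord`.

    Unknown fields are rejected; missing or unparseable fields raise
    :class:`~skillnudge.errors.SchemaError` naming the field, an out-of-domain
    mood raises :class:`~skillnudge.errors.RangeError`, and cross-field
    contradictions raise :class:`~skillnudge.errors.ConsistencyError`.
    """
    try:
        return EntryRecord.model_validate(dict(raw))
    except pydantic.ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc']) or '<record>'}: {e['msg']}"
            for e in exc.errors()
        )
        raise SchemaError(f"invalid entry record: {details}") from exc


class PriorityGoal(BaseModel):
    """A clinician-set weekly goal, typically linked to one of the six skills.

    Only skills with an active priority goal may receive momentary
    interventions; the goal's ``linked_template_ids`` enumerate the content the
    clinician selected for it. ``scaled_target`` holds optional scaled-down
    parameters (e.g. ``{"meals_per_day": 2, "snacks_per_day": 1}`` while the
    patient builds up to the full regular-eating pattern).
    """

    model_config = ConfigDict(extra="forbid")

    goal_id: str
    description: str = ""
    skill: Optional[Skill] = None
    scaled_target: Optional[dict[str, Any]] = None
    linked_template_ids: tuple[str, ...] = ()
    active_from: Optional[dt.date] = None
    active_to: Optional[dt.date] = None
    weekly_success_rating: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "PriorityGoal":
        if self.weekly_success_rating is not None and not (
            1 <= self.weekly_success_rating <= 5
        ):
            raise RangeError("weekly_success_rating must be in 1..5")
        return self


class InterventionTemplate(BaseModel):
    """Three-part momentary intervention content.

    Every intervention names the skill to practice now, a brief rationale for
    why this moment is an opportunity, and concrete try-this-out-now
    instructions; all three parts must be nonempty.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    template_id: str
    skill: Skill
    barrier: Barrier = Barrier.low_accountability
    strategy_text: str
    rationale_text: str
    try_now_text: str
    is_custom: bool = False

    @model_validator(mode="after")
    def _check(self) -> "InterventionTemplate":
        for f in ("strategy_text", "rationale_text", "try_now_text"):
            if not getattr(self, f).strip():
                raise ConsistencyError(f"intervention template {f} must be nonempty")
        return self


class DeliveredIntervention(BaseModel):
    """Audit record of one delivered intervention and the patient's response.

    ``skill`` and ``goal_id`` are denormalized at delivery time so the record
    is self-describing for the clinician portal and the analytics; custom push
    deliveries may carry no skill at all (e.g. motivational messages). A
    decline reason is present exactly when the patient says they do not intend
    to use the suggested skill.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    delivery_id: str
    patient_id: str
    timestamp: dt.datetime
    trigger: Trigger
    template_id: Optional[str] = None
    skill: Optional[Skill] = None
    goal_id: Optional[str] = None
    source_entry_id: Optional[str] = None
    intends_to_use: Optional[bool] = None
    decline_reason: Optional[DeclineReason] = None

    @model_validator(mode="after")
    def _check(self) -> "DeliveredIntervention":
        if self.intends_to_use is False and self.decline_reason is None:
            raise ConsistencyError("a declined intervention requires a reason")
        if self.decline_reason is not None and self.intends_to_use is not False:
            raise ConsistencyError(
                "decline_reason is only valid when intends_to_use is false"
            )
        return self


class PatientConfig(BaseModel):
    """Clinician-adjustable per-patient algorithm settings.

    ``regular_eating_gap_h`` is the waking-hours gap without an eating episode
    that cues the regular-eating rule (default 5), and
    ``monitoring_reminder_gap_h`` the waking-hours silence after which a
    self-monitoring reminder push is due (default 5, clinician adjustable).
    ``per_skill_min_gap_h`` rate-limits repeat interventions per skill; unset
    skills default to 0 (fire whenever triggered) except regular eating, which
    defaults to the eating-gap itself so one long gap cannot fire twice on
    back-to-back entries.
    """

    model_config = ConfigDict(extra="forbid")

    patient_id: str = "patient"
    waking_window: tuple[dt.time, dt.time] = (dt.time(8, 0), dt.time(23, 0))
    monitoring_reminder_gap_h: float = 5.0
    regular_eating_gap_h: float = 5.0
    mood_trigger_threshold: int = 4
    per_skill_min_gap_h: dict[Skill, float] = {}
    goal_priority_order: tuple[str, ...] = ()
    opened_skills: set[Skill] = set()

    @field_serializer("opened_skills")
    def _ser_opened(self, v: set[Skill]) -> list[str]:
        return _sorted_enum_list(v)

    @model_validator(mode="after")
    def _check(self) -> "PatientConfig":
        start, end = self.waking_window
        if start >= end:
            raise ConfigurationError("waking_window start must precede end")
        if self.monitoring_reminder_gap_h <= 0 or self.regular_eating_gap_h <= 0:
            raise ConfigurationError("gap hours must be positive")
        if not (2 <= self.mood_trigger_threshold <= 5):
            raise RangeError("mood_trigger_threshold must be in 2..5")
        if any(v < 0 for v in self.per_skill_min_gap_h.values()):
            raise ConfigurationError("per-skill minimum gaps must be >= 0")
        return self

    def skill_min_gap(self, skill: Skill) -> float:
        """Effective minimum re-delivery gap (wall-clock hours) for a skill."""
        if skill in self.per_skill_min_gap_h:
            return self.per_skill_min_gap_h[skill]
        if skill is Skill.REGULAR_EATING:
            return self.regular_eating_gap_h
        return 0.0


@dataclass
class EngineState:
    """Mutable running state the online algorithm consults.

    Times are monotone non-decreasing as entries are processed in order.
    ``rotation_cursor_by_goal`` drives round-robin rotation over each goal's
    linked templates so repeat triggers see varied content.
    """

    last_entry_time: Optional[dt.datetime] = None
    last_eating_episode_time: Optional[dt.datetime] = None
    last_delivery_time_by_skill: dict[Skill, dt.datetime] = field(default_factory=dict)
    rotation_cursor_by_goal: dict[str, int] = field(default_factory=dict)
    deliveries_by_skill: Counter = field(default_factory=Counter)
    total_deliveries: int = 0

    def copy(self) -> "EngineState":
        return EngineState(
            last_entry_time=self.last_entry_time,
            last_eating_episode_time=self.last_eating_episode_time,
            last_delivery_time_by_skill=dict(self.last_delivery_time_by_skill),
            rotation_cursor_by_goal=dict(self.rotation_cursor_by_goal),
            deliveries_by_skill=Counter(self.deliveries_by_skill),
            total_deliveries=self.total_deliveries,
        )


@dataclass(frozen=True)
class TriggerCandidate:
    """A detected skill-practice opportunity, before goal gating."""

    skill: Skill
    trigger: Trigger
    source_entry_id: str
    rationale_key: str


class GoalSegment(BaseModel):
    """Goals in force from ``start`` (inclusive) to ``end`` (exclusive).

    One segment per clinician visit; ``end`` is None for the currently open
    segment. At most 3 goals may be active at once.
    """

    model_config = ConfigDict(extra="forbid")

    start: dt.date
    end: Optional[dt.date] = None
    goals: tuple[PriorityGoal, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "GoalSegment":
        if len(self.goals) > 3:
            raise LimitError("at most 3 priority goals may be active at once")
        if self.end is not None and self.end <= self.start:
            raise ConfigurationError("segment end must follow start")
        return self


class GoalsTimeline(BaseModel):
    """Ordered, non-overlapping sequence of goal segments."""

    model_config = ConfigDict(extra="forbid")

    segments: tuple[GoalSegment, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "GoalsTimeline":
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end is None or a.end > b.start:
                raise ConfigurationError("goal segments must be ordered and disjoint")
        return self

    def active_goals(self, day: dt.date) -> tuple[PriorityGoal, ...]:
        for seg in self.segments:
            if seg.start <= day and (seg.end is None or day < seg.end):
                return seg.goals
        return ()

    @property
    def start(self) -> Optional[dt.date]:
        return self.segments[0].start if self.segments else None
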