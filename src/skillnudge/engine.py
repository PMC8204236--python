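"""The clinician-controlled momentary decision algorithm.

At every self-monitoring entry the engine runs three stages:

1. :func:`detect_candidates` — evaluate the rule set against the entry and the
   running state, yielding every skill-practice opportunity the log evidences
   (an over-long gap without eating, an unmanaged urge, a bad unmanaged mood,
   an insufficient meal, a skipped feared food, a logged symptom).
2. :func:`gate_by_goals` — keep only opportunities whose skill carries a
   currently active clinician-set priority goal. This is the clinician's main
   control surface: no goal, no intervention, even if the opportunity is real.
3. :func:`select_intervention` — pick at most ONE winner per entry (rate
   limits per skill, then clinician goal priority, then a fixed
   restraint-first skill precedence), rotate round-robin through the winning
   goal's linked content, and emit the delivery record.

The engine is fully deterministic: identical inputs produce identical
deliveries, and :func:`run_engine` batch-replays a log exactly as online
processing would have.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Optional, Sequence

from .errors import ConfigurationError, ConsistencyError, OrderingError
from .models import (
    SKILL_PRECEDENCE,
    DeliveredIntervention,
    EngineState,
    EntryRecord,
    GoalsTimeline,
    InterventionTemplate,
    PatientConfig,
    PriorityGoal,
    Skill,
    Trigger,
    TriggerCandidate,
)
from .scheduler import waking_hours_between

__all__ = [
    "detect_candidates",
    "gate_by_goals",
    "select_intervention",
    "record_response",
    "run_engine",
    "advance_state",
]

_PRECEDENCE_INDEX = {s: i for i, s in enumerate(SKILL_PRECEDENCE)}


def detect_candidates(
    entry: EntryRecord, state: EngineState, config: PatientConfig
) -> list[TriggerCandidate]:
    """All skill-practice opportunities this entry evidences, before gating.

    Rules (only skills in ``config.opened_skills`` are considered):

    - regular eating: at this entry's timestamp, >= ``regular_eating_gap_h``
      waking hours have passed since the last *logged* eating episode;
    - eat enough: a non-loss-of-control eating episode where the patient said
      "no" to eating enough or to covering a range of macronutrients;
    - feared foods: an eating episode where the clinician-enabled
      ``included_feared_food`` question was answered "no";
    - urge management: an urge is present and no urge strategy was used;
    - mood management: mood at or above the trigger threshold and the patient
      explicitly checked that no mood strategy was used;
    - trigger awareness: any behavior or urge was logged (a symptom is the
      natural moment to reflect on its trigger).

    The returned list is ordered by the fixed skill precedence. State is not
    mutated; call :func:`advance_state` after detection.
    """
    if state.last_entry_time is not None and entry.timestamp < state.last_entry_time:
        raise OrderingError(
            f"entry {entry.entry_id} at {entry.timestamp} precedes "
            f"already-processed {state.last_entry_time}"
        )
    cands: list[TriggerCandidate] = []

    if state.last_eating_episode_time is not None:
        gap = waking_hours_between(
            state.last_eating_episode_time, entry.timestamp, config.waking_window
        )
        if gap >= config.regular_eating_gap_h:
            cands.append(
                TriggerCandidate(
                    Skill.REGULAR_EATING,
                    Trigger.regular_eating_gap,
                    entry.entry_id,
                    f"{gap:.1f} waking hours without an eating episode",
                )
            )

    if (
        entry.is_eating_episode
        and not entry.loss_of_control
        and (entry.ate_enough is False or entry.ate_macro_range is False)
    ):
        cands.append(
            TriggerCandidate(
                Skill.EAT_ENOUGH,
                Trigger.eat_enough,
                entry.entry_id,
                "episode reported as not enough food or too narrow a range",
            )
        )

    if entry.is_eating_episode and entry.included_feared_food is False:
        cands.append(
            TriggerCandidate(
                Skill.FEARED_FOODS,
                Trigger.feared_food,
                entry.entry_id,
                "no feared food included in this episode",
            )
        )

    if entry.urge_present and entry.used_urge_strategy is not True:
        cands.append(
            TriggerCandidate(
                Skill.URGE_MANAGEMENT,
                Trigger.urge,
                entry.entry_id,
                "urge reported without an urge management strategy",
            )
        )

    if (
        entry.mood is not None
        and entry.mood >= config.mood_trigger_threshold
        and entry.used_mood_strategy is False
    ):
        cands.append(
            TriggerCandidate(
                Skill.MOOD_MANAGEMENT,
                Trigger.mood,
                entry.entry_id,
                f"mood {entry.mood}/5 without a mood management strategy",
            )
        )

    if entry.behaviors or entry.urge_present:
        cands.append(
            TriggerCandidate(
                Skill.TRIGGER_AWARENESS,
                Trigger.trigger_awareness,
                entry.entry_id,
                "a behavior or urge was logged",
            )
        )

    cands = [c for c in cands if c.skill in config.opened_skills]
    cands.sort(key=lambda c: _PRECEDENCE_INDEX[c.skill])
    return cands


def gate_by_goals(
    candidates: Sequence[TriggerCandidate], active_goals: Sequence[PriorityGoal]
) -> list[TriggerCandidate]:
    """Keep only candidates whose skill has an active priority goal.

    A real practice opportunity with no matching goal is deliberately ignored:
    the patient and clinician are not working on that skill yet.
    """
    goal_skills = {g.skill for g in active_goals if g.skill is not None}
    return [c for c in candidates if c.skill in goal_skills]


def _goal_rank(goal: PriorityGoal, order: Sequence[str]) -> tuple:
    # goals the clinician did not rank are all tied behind the ranked ones;
    # the fixed skill precedence then decides among them
    try:
        return (0, order.index(goal.goal_id))
    except ValueError:
        return (1, 0)


def select_intervention(
    gated: Sequence[TriggerCandidate],
    goals: Sequence[PriorityGoal],
    templates: Mapping[str, InterventionTemplate],
    state: EngineState,
    config: PatientConfig,
    now: dt.datetime,
) -> Optional[DeliveredIntervention]:
    """Choose and emit at most one intervention from the gated candidates.

    Selection: (1) drop candidates whose skill was intervened on within its
    minimum re-delivery gap of ``now`` (wall-clock hours); (2) rank the rest by
    the clinician's goal priority order, breaking ties with the fixed
    restraint-first skill precedence; (3) rotate round-robin through the
    winning goal's linked templates; (4) emit the delivery and update state.

    Raises :class:`~skillnudge.errors.ConfigurationError` if the winning goal
    has no linked templates.
    """
    eligible: list[TriggerCandidate] = []
    for cand in gated:
        last = state.last_delivery_time_by_skill.get(cand.skill)
        min_gap = config.skill_min_gap(cand.skill)
        if last is not None and (now - last).total_seconds() / 3600.0 < min_gap:
            continue
        eligible.append(cand)
    if not eligible:
        return None

    best: Optional[tuple[tuple, TriggerCandidate, PriorityGoal]] = None
    for cand in eligible:
        for goal in goals:
            if goal.skill is not cand.skill:
                continue
            rank = (
                _goal_rank(goal, config.goal_priority_order),
                _PRECEDENCE_INDEX[cand.skill],
            )
            if best is None or rank < best[0]:
                best = (rank, cand, goal)
    if best is None:
        return None
    _, winner, goal = best

    if not goal.linked_template_ids:
        raise ConfigurationError(
            f"priority goal {goal.goal_id!r} has no linked intervention templates"
        )
    cursor = state.rotation_cursor_by_goal.get(goal.goal_id, 0)
    template_id = goal.linked_template_ids[cursor % len(goal.linked_template_ids)]
    if template_id not in templates:
        raise ConfigurationError(f"unknown intervention template {template_id!r}")

    state.rotation_cursor_by_goal[goal.goal_id] = cursor + 1
    state.last_delivery_time_by_skill[winner.skill] = now
    state.deliveries_by_skill[winner.skill] += 1
    state.total_deliveries += 1

    return DeliveredIntervention(
        delivery_id=f"{config.patient_id}-d{state.total_deliveries:05d}",
        patient_id=config.patient_id,
        timestamp=now,
        trigger=winner.trigger,
        template_id=template_id,
        skill=winner.skill,
        goal_id=goal.goal_id,
        source_entry_id=winner.source_entry_id,
    )


def record_response(
    delivery: DeliveredIntervention,
    intends: bool,
    reason: Optional[str] = None,
) -> DeliveredIntervention:
    """Attach the patient's intend-to-use answer to a delivery.

    A reason may (and must) accompany only a "no". Re-answering an already
    answered delivery is an error.
    """
    if delivery.intends_to_use is not None:
        raise ConsistencyError(
            f"delivery {delivery.delivery_id} already has a recorded response"
        )
    if intends and reason is not None:
        raise ConsistencyError("a decline reason is only valid with intends=False")
    # full re-validation enforces the decline-reason-iff-declined invariant
    return DeliveredIntervention.model_validate(
        {
            **delivery.model_dump(),
            "intends_to_use": intends,
            "decline_reason": reason,
        }
    )


def advance_state(state: EngineState, entry: EntryRecord) -> None:
    """Fold a processed entry into the running state (after detection)."""
    state.last_entry_time = entry.timestamp
    if entry.is_eating_episode:
        state.last_eating_episode_time = entry.timestamp


def run_engine(
    log: Sequence[EntryRecord],
    config: PatientConfig,
    goals_timeline: GoalsTimeline,
    templates: Mapping[str, InterventionTemplate],
    state: Optional[EngineState] = None,
) -> tuple[list[DeliveredIntervention], EngineState]:
    """Batch-replay a time-sorted log through the online algorithm.

    Deterministic, and identical to processing the entries one at a time as
    they arrive. Returns the deliveries and the final engine state.
    """
    state = state if state is not None else EngineState()
    deliveries: list[DeliveredIntervention] = []
    for entry in log:
        active = goals_timeline.active_goals(entry.timestamp.date())
        candidates = detect_candidates(entry, state, config)
        gated = gate_by_goals(candidates, active)
        delivery = select_intervention(
            gated, active, templates, state, config, now=entry.timestamp
        )
        advance_state(state, entry)
        if delivery is not None:
            deliveries.append(delivery)
    return deliveries, state
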