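"""Stateless brute-force oracle for the decision engine, plus a randomized
scenario generator.

The oracle re-derives every decision for entry *i* from scratch — scanning the
raw log prefix for the last eating episode, its own already-emitted deliveries
for rate limits and round-robin cursors — with no incremental state and no
imports from the engine module. It is deliberately a second, independent
implementation of the decision rules.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

from skillnudge.models import (
    Behavior,
    EntryKind,
    EntryRecord,
    GoalSegment,
    GoalsTimeline,
    InterventionTemplate,
    PatientConfig,
    PriorityGoal,
    Skill,
)

# fixed restraint-first precedence, restated independently
_PREC = [
    Skill.REGULAR_EATING,
    Skill.EAT_ENOUGH,
    Skill.FEARED_FOODS,
    Skill.URGE_MANAGEMENT,
    Skill.MOOD_MANAGEMENT,
    Skill.TRIGGER_AWARENESS,
]
_TRIG = {
    Skill.REGULAR_EATING: "regular_eating_gap",
    Skill.EAT_ENOUGH: "eat_enough",
    Skill.FEARED_FOODS: "feared_food",
    Skill.URGE_MANAGEMENT: "urge",
    Skill.MOOD_MANAGEMENT: "mood",
    Skill.TRIGGER_AWARENESS: "trigger_awareness",
}


def _waking_hours(t1: dt.datetime, t2: dt.datetime, window) -> float:
    """Independent waking-time measure: clip each day's overlap."""
    start, end = window
    total = dt.timedelta()
    day = t1.date()
    while day <= t2.date():
        lo = max(t1, dt.datetime.combine(day, start))
        hi = min(t2, dt.datetime.combine(day, end))
        if hi > lo:
            total += hi - lo
        day += dt.timedelta(days=1)
    return total.total_seconds() / 3600.0


def brute_force_deliveries(
    log: list[EntryRecord],
    config: PatientConfig,
    timeline: GoalsTimeline,
    templates: dict[str, InterventionTemplate],
) -> list[tuple]:
    """Replay the decision rules statelessly.

    Returns one key tuple per delivery:
    (timestamp, trigger, skill, goal_id, template_id, source_entry_id).
    """
    deliveries: list[tuple] = []
    for i, entry in enumerate(log):
        now = entry.timestamp
        active = timeline.active_goals(now.date())

        # --- detect, straight from the rules
        skills: list[Skill] = []
        prior_eps = [e.timestamp for e in log[:i] if e.is_eating_episode]
        if prior_eps:
            gap = _waking_hours(max(prior_eps), now, config.waking_window)
            if gap >= config.regular_eating_gap_h:
                skills.append(Skill.REGULAR_EATING)
        if (
            entry.is_eating_episode
            and not entry.loss_of_control
            and (entry.ate_enough is False or entry.ate_macro_range is False)
        ):
            skills.append(Skill.EAT_ENOUGH)
        if entry.is_eating_episode and entry.included_feared_food is False:
            skills.append(Skill.FEARED_FOODS)
        if entry.urge_present and entry.used_urge_strategy is not True:
            skills.append(Skill.URGE_MANAGEMENT)
        if (
            entry.mood is not None
            and entry.mood >= config.mood_trigger_threshold
            and entry.used_mood_strategy is False
        ):
            skills.append(Skill.MOOD_MANAGEMENT)
        if entry.behaviors or entry.urge_present:
            skills.append(Skill.TRIGGER_AWARENESS)
        skills = [s for s in skills if s in config.opened_skills]

        # --- gate by active goals
        goal_skills = {g.skill for g in active if g.skill is not None}
        skills = [s for s in skills if s in goal_skills]

        # --- rate limit against already-emitted deliveries (wall hours)
        def min_gap(s: Skill) -> float:
            if s in config.per_skill_min_gap_h:
                return config.per_skill_min_gap_h[s]
            return config.regular_eating_gap_h if s is Skill.REGULAR_EATING else 0.0

        eligible = []
        for s in skills:
            prior = [d for d in deliveries if d[2] is s]
            if prior:
                hours = (now - max(d[0] for d in prior)).total_seconds() / 3600.0
                if hours < min_gap(s):
                    continue
            eligible.append(s)
        if not eligible:
            continue

        # --- rank: clinician goal order, then fixed precedence
        order = list(config.goal_priority_order)
        best = None
        for s in eligible:
            for goal in active:
                if goal.skill is not s:
                    continue
                grank = (
                    (0, order.index(goal.goal_id))
                    if goal.goal_id in order
                    else (1, 0)
                )
                rank = (grank, _PREC.index(s))
                if best is None or rank < best[0]:
                    best = (rank, s, goal)
        if best is None:
            continue
        _, skill, goal = best

        # --- round robin over the goal's linked templates
        cursor = sum(1 for d in deliveries if d[3] == goal.goal_id)
        template_id = goal.linked_template_ids[cursor % len(goal.linked_template_ids)]
        deliveries.append(
            (now, _TRIG[skill], skill, goal.goal_id, template_id, entry.entry_id)
        )
    return deliveries


def delivery_key(d) -> tuple:
    """Comparable key for an engine DeliveredIntervention."""
    return (
        d.timestamp,
        d.trigger.value,
        d.skill,
        d.goal_id,
        d.template_id,
        d.source_entry_id,
    )


# --- randomized scenarios ----------------------------------------------------

_MEALS = [k for k in EntryKind if k is not EntryKind.other]


def random_scenario(rng: np.random.Generator, max_entries: int = 250):
    """Random but valid (log, config, timeline, templates) tuple."""
    window = (dt.time(int(rng.integers(6, 10)), 0), dt.time(int(rng.integers(21, 24)), 0))
    all_skills = list(Skill)
    opened = {s for s in all_skills if rng.random() < 0.7}
    config = PatientConfig(
        patient_id="rand",
        waking_window=window,
        regular_eating_gap_h=float(rng.choice([3.0, 4.0, 5.0, 6.0])),
        mood_trigger_threshold=int(rng.integers(2, 6)),
        per_skill_min_gap_h={
            s: float(rng.choice([0.0, 1.0, 4.0, 12.0]))
            for s in all_skills
            if rng.random() < 0.5
        },
        opened_skills=opened,
    )

    templates: dict[str, InterventionTemplate] = {}
    start = dt.date(2024, 3, 1)
    segments = []
    n_segments = int(rng.integers(1, 7))
    goal_counter = 0
    seg_start = start
    for _ in range(n_segments):
        seg_len = int(rng.integers(5, 15))
        n_goals = int(rng.integers(0, 4))
        goal_skills = [all_skills[i] for i in rng.permutation(len(all_skills))[:n_goals]]
        goals = []
        for s in goal_skills:
            goal_counter += 1
            tids = []
            for j in range(int(rng.integers(1, 4))):
                tid = f"t{goal_counter}-{j}"
                templates[tid] = InterventionTemplate(
                    template_id=tid,
                    skill=s,
                    strategy_text=f"strategy {tid}",
                    rationale_text=f"rationale {tid}",
                    try_now_text=f"try {tid}",
                )
                tids.append(tid)
            goals.append(
                PriorityGoal(
                    goal_id=f"g{goal_counter}",
                    skill=s,
                    linked_template_ids=tuple(tids),
                )
            )
        seg_end = seg_start + dt.timedelta(days=seg_len)
        segments.append(
            GoalSegment(start=seg_start, end=seg_end, goals=tuple(goals))
        )
        seg_start = seg_end
    timeline = GoalsTimeline(segments=tuple(segments))
    # clinician priority order: a random subset/permutation of goal ids
    gids = [g.goal_id for seg in segments for g in seg.goals]
    order = [g for g in rng.permutation(gids) if rng.random() < 0.8]
    config = config.model_copy(update={"goal_priority_order": tuple(order)})

    n_entries = int(rng.integers(5, max_entries + 1))
    t = dt.datetime.combine(start, dt.time(8, 0))
    behaviors_pool = list(Behavior)
    log: list[EntryRecord] = []
    for i in range(n_entries):
        t = t + dt.timedelta(hours=float(rng.uniform(0.5, 9.0)))
        if t.date() >= seg_start + dt.timedelta(days=3):
            break
        kind = (
            EntryKind.other
            if rng.random() < 0.2
            else _MEALS[int(rng.integers(0, len(_MEALS)))]
        )
        mood = int(rng.integers(1, 6))
        urge = bool(rng.random() < 0.35)
        behaviors = frozenset(
            b for b in behaviors_pool if rng.random() < 0.08
        )
        eating = kind is not EntryKind.other or bool(rng.random() < 0.2)
        fields = dict(
            entry_id=f"e{i:04d}",
            patient_id="rand",
            timestamp=t,
            entry_kind=kind,
            is_eating_episode=True if kind is not EntryKind.other else eating,
            loss_of_control=bool(rng.random() < 0.5) and Behavior.binge in behaviors,
            behaviors=behaviors,
            urge_present=urge,
            urge_target=(
                behaviors_pool[int(rng.integers(0, len(behaviors_pool)))]
                if urge and rng.random() < 0.7
                else None
            ),
            mood=mood,
            used_mood_strategy=bool(rng.random() < 0.5) if rng.random() < 0.7 else None,
            used_urge_strategy=(
                bool(rng.random() < 0.5) if urge and rng.random() < 0.8 else None
            ),
        )
        if fields["is_eating_episode"]:
            for f in ("ate_enough", "ate_macro_range", "included_feared_food"):
                if rng.random() < 0.6:
                    fields[f] = bool(rng.random() < 0.6)
        log.append(EntryRecord(**fields))
    return log, config, timeline, templates
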