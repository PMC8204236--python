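"""Synthetic patient simulator.

Generates self-monitoring event logs with the statistical structure of a real
outpatient course: roughly three entries per day drawn from a six-slot
meal/snack schedule plus occasional *other* entries, most but not all days
covered, adherence drifting down over the 16 treatment weeks, urges and
behaviors at clinically plausible rates, and skill use that improves as
momentary interventions accumulate.

The simulation is closed-loop: each generated entry is pushed through the real
decision engine, and the probability that the patient uses a skill follows a
saturating dose-response on the cumulative interventions received for that
skill,

    p(I) = p0 + (p_max - p0) * (1 - exp(-k * I)),

the simplest monotone learning model with interpretable parameters (baseline,
ceiling, learning rate per intervention). The latent per-day skill-use
probabilities are returned alongside the log so recovery studies can compare
estimates with truth. Everything is reproducible from the seed.

This model exists to exercise the software; it makes no claim of clinical
validity.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .clinician import Visit, close_visit, open_skill, set_visit_goals
from .engine import advance_state, detect_candidates, gate_by_goals, record_response, select_intervention
from .errors import SimulationError
from .models import (
    Behavior,
    DeclineReason,
    DeliveredIntervention,
    EngineState,
    EntryKind,
    EntryRecord,
    GoalsTimeline,
    InterventionTemplate,
    PatientConfig,
    PriorityGoal,
    Skill,
)

__all__ = [
    "SimParams",
    "SimResult",
    "pilot_preset",
    "default_templates",
    "pilot_goals_timeline",
    "simulate_patient",
    "simulate_cohort",
    "learning_recovery_study",
]

#: Daily meal/snack slot schedule (entry kind, clock time).
DEFAULT_MEAL_SLOTS: tuple[tuple[EntryKind, dt.time], ...] = (
    (EntryKind.breakfast, dt.time(8, 0)),
    (EntryKind.midmorning_snack, dt.time(10, 30)),
    (EntryKind.lunch, dt.time(12, 30)),
    (EntryKind.midafternoon_snack, dt.time(15, 30)),
    (EntryKind.dinner, dt.time(18, 30)),
    (EntryKind.evening_snack, dt.time(21, 0)),
)

_SLOT_FOODS: dict[EntryKind, tuple[str, ...]] = {
    EntryKind.breakfast: ("oatmeal", "eggs and toast", "yogurt and granola"),
    EntryKind.midmorning_snack: ("apple", "granola bar", "crackers"),
    EntryKind.lunch: ("sandwich", "salad with chicken", "leftover pasta"),
    EntryKind.midafternoon_snack: ("trail mix", "banana", "cheese and crackers"),
    EntryKind.dinner: ("stir fry", "burrito bowl", "pizza slices"),
    EntryKind.evening_snack: ("ice cream", "popcorn", "cookies"),
}


class SimParams(BaseModel):
    """Generative parameters of the synthetic patient behavior model.

    Defaults (see :func:`pilot_preset`) target the observed course of a
    16-week outpatient pilot: ~3 entries/day declining modestly over time,
    ~86% of days with at least one entry, and roughly 40% attrition over 16
    weeks. ``skill_learning`` is the (p0, p_max, k) of the saturating
    dose-response on cumulative per-skill interventions.
    """

    model_config = ConfigDict(extra="forbid")

    weeks: int = 16
    p_log_entry: float = 0.85
    p_skip_meal: float = 0.30
    p_miss_day: float = 0.13
    p_other_event: float = 0.30
    p_urge_base: float = 0.15
    p_behavior_given_urge: float = 0.40
    mood_dist: tuple[float, float, float, float, float] = (0.15, 0.30, 0.30, 0.17, 0.08)
    skill_learning: tuple[float, float, float] = (0.2, 0.8, 0.05)
    adherence_decay: float = 0.985
    p_dropout_weekly: float = 0.03
    p_intend: float = 0.97
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimParams":
        probs = {
            "p_log_entry": self.p_log_entry,
            "p_skip_meal": self.p_skip_meal,
            "p_miss_day": self.p_miss_day,
            "p_other_event": self.p_other_event,
            "p_urge_base": self.p_urge_base,
            "p_behavior_given_urge": self.p_behavior_given_urge,
            "adherence_decay": self.adherence_decay,
            "p_dropout_weekly": self.p_dropout_weekly,
            "p_intend": self.p_intend,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1], got {p}")
        if self.weeks < 1:
            raise SimulationError("weeks must be >= 1")
        if abs(sum(self.mood_dist) - 1.0) > 1e-9:
            raise SimulationError("mood_dist must sum to 1")
        p0, p_max, k = self.skill_learning
        if not (0.0 <= p0 <= p_max <= 1.0) or k < 0:
            raise SimulationError("skill_learning requires 0 <= p0 <= p_max <= 1, k >= 0")
        return self


@dataclass
class SimResult:
    """One simulated patient: log, deliveries, latent truth, and metadata."""

    entries: list[EntryRecord]
    deliveries: list[DeliveredIntervention]
    latent: pd.DataFrame
    start_date: dt.date
    dropout_week: Optional[int]
    params: SimParams
    config: PatientConfig
    goals_timeline: GoalsTimeline
    templates: dict[str, InterventionTemplate] = field(default_factory=dict)

    @property
    def period(self) -> tuple[dt.date, dt.date]:
        """Enrollment period truncated at dropout (inclusive dates)."""
        weeks_active = (
            self.params.weeks if self.dropout_week is None else self.dropout_week - 1
        )
        end = self.start_date + dt.timedelta(days=7 * weeks_active - 1)
        return (self.start_date, end)


def pilot_preset(**overrides) -> SimParams:
    """Default 16-week outpatient scenario parameters."""
    return SimParams(**overrides)


def default_templates() -> dict[str, InterventionTemplate]:
    """Two prewritten three-part interventions per skill."""
    texts: dict[Skill, list[tuple[str, str, str]]] = {
        Skill.REGULAR_EATING: [
            (
                "Stick to your planned meal and snack schedule, even if you are "
                "worried it is too much food.",
                "Getting back on track after a missed meal or snack often takes "
                "some problem solving.",
                "Think through how you will meet your regular eating goals for "
                "the rest of today and work around any logistical barriers.",
            ),
            (
                "Plan your next eating episode right now.",
                "Long gaps without eating increase vulnerability to binge "
                "eating later in the day.",
                "Set a time and a place for your next meal or snack within the "
                "next few hours and put a reminder in your phone.",
            ),
        ],
        Skill.EAT_ENOUGH: [
            (
                "Eat enough at each meal and snack to prevent acute hunger.",
                "Under-eating now makes a binge later much more likely.",
                "At your next eating episode, add one item so the meal carries "
                "you comfortably to the next planned episode.",
            ),
            (
                "Cover a range of macronutrients at each eating episode.",
                "Meals with protein, fat, and carbohydrate are more satiating "
                "and reduce feelings of deprivation.",
                "Check your next plate: does it include all three? If not, add "
                "what is missing.",
            ),
        ],
        Skill.FEARED_FOODS: [
            (
                "Include one feared or avoided food in a planned eating episode.",
                "Practicing with feared foods weakens rigid food rules and "
                "reduces deprivation-driven binges.",
                "Pick one item from your feared-foods list and plan exactly "
                "when you will eat a normal portion of it today or tomorrow.",
            ),
            (
                "Challenge one food rule today.",
                "Food rules maintain restraint, and restraint maintains binge "
                "eating.",
                "Identify the rule behind a food you avoided today and plan a "
                "small, deliberate exception.",
            ),
        ],
        Skill.URGE_MANAGEMENT: [
            (
                "Ride out the urge without acting on it.",
                "Urges crest and pass like waves; acting on them reinforces "
                "the cycle.",
                "Set a 15-minute timer and do something engaging with your "
                "hands until it rings, then re-rate the urge.",
            ),
            (
                "Use an alternative activity from your list.",
                "Replacing the behavior with a competing activity breaks the "
                "urge-behavior link.",
                "Pick one activity from the list you built in session and "
                "start it now, before deciding anything else.",
            ),
        ],
        Skill.TRIGGER_AWARENESS: [
            (
                "Name the trigger behind what you just logged.",
                "Spotting internal and external triggers early is the first "
                "step to interrupting the chain toward a binge.",
                "Write one sentence in the comment box: what happened right "
                "before this urge or behavior?",
            ),
            (
                "Scan your environment for binge cues.",
                "External cues like palatable food left in sight reliably "
                "precede symptoms.",
                "Take 2 minutes to remove or avoid one cue you can control "
                "right now.",
            ),
        ],
        Skill.MOOD_MANAGEMENT: [
            (
                "Engage in alternative activities to improve your mood.",
                "Breaking problematic habits means tolerating uncomfortable "
                "feelings instead of eating in response to them.",
                "Reflect on your long-term goals, then start one alternative "
                "activity from our list right now.",
            ),
            (
                "Use a brief mood-repair strategy.",
                "Negative affect is the most common internal trigger for "
                "binge eating.",
                "Try 10 slow breaths or a 10-minute walk, then re-rate your "
                "mood in your next entry.",
            ),
        ],
    }
    prefix = {
        Skill.REGULAR_EATING: "re",
        Skill.EAT_ENOUGH: "ee",
        Skill.FEARED_FOODS: "ff",
        Skill.URGE_MANAGEMENT: "um",
        Skill.TRIGGER_AWARENESS: "ta",
        Skill.MOOD_MANAGEMENT: "mm",
    }
    out: dict[str, InterventionTemplate] = {}
    for skill, items in texts.items():
        for i, (strategy, rationale, try_now) in enumerate(items, start=1):
            tid = f"{prefix[skill]}-{i}"
            out[tid] = InterventionTemplate(
                template_id=tid,
                skill=skill,
                strategy_text=strategy,
                rationale_text=rationale,
                try_now_text=try_now,
            )
    return out


#: Which skills carry a priority goal in each phase of the default course.
_PILOT_PHASES: tuple[tuple[int, tuple[Skill, ...]], ...] = (
    (1, (Skill.REGULAR_EATING,)),
    (3, (Skill.REGULAR_EATING, Skill.EAT_ENOUGH)),
    (5, (Skill.REGULAR_EATING, Skill.EAT_ENOUGH, Skill.URGE_MANAGEMENT)),
    (9, (Skill.REGULAR_EATING, Skill.URGE_MANAGEMENT, Skill.MOOD_MANAGEMENT)),
    (13, (Skill.REGULAR_EATING, Skill.EAT_ENOUGH, Skill.MOOD_MANAGEMENT)),
)

_GOAL_DESCRIPTIONS: dict[Skill, str] = {
    Skill.REGULAR_EATING: "Eat regular meals and snacks",
    Skill.EAT_ENOUGH: "Eat enough at each meal and snack",
    Skill.FEARED_FOODS: "Incorporate one feared food this week",
    Skill.URGE_MANAGEMENT: "Practice urge management whenever you experience an urge",
    Skill.TRIGGER_AWARENESS: "Notice and record your binge triggers",
    Skill.MOOD_MANAGEMENT: "Learn to manage negative emotions",
}


def pilot_goals_timeline(
    start_date: dt.date,
    weeks: int = 16,
    config: Optional[PatientConfig] = None,
    templates: Optional[dict[str, InterventionTemplate]] = None,
) -> tuple[PatientConfig, GoalsTimeline, dict[str, InterventionTemplate]]:
    """Build the default treatment course via the clinician workflow.

    Restraint skills are introduced first (regular eating from week 1), cue
    skills in the latter half, mirroring how the treatment sequences its
    content; each phase's goals are set and closed as a visit.
    """
    config = config if config is not None else PatientConfig()
    templates = templates if templates is not None else default_templates()
    timeline = GoalsTimeline()
    by_skill: dict[Skill, list[str]] = {}
    for tid, tpl in templates.items():
        by_skill.setdefault(tpl.skill, []).append(tid)
    for i, (week, skills) in enumerate(_PILOT_PHASES):
        if week > weeks:
            break
        for skill in skills:
            config = open_skill(config, skill)
        visit = Visit(
            visit_id=f"v{i + 1}", date=start_date + dt.timedelta(days=7 * (week - 1))
        )
        goals = [
            PriorityGoal(
                goal_id=f"g{i + 1}-{skill.value.lower()}",
                skill=skill,
                description=_GOAL_DESCRIPTIONS[skill],
                linked_template_ids=tuple(sorted(by_skill[skill])),
            )
            for skill in skills
        ]
        set_visit_goals(visit, goals, config)
        config, timeline = close_visit(visit, config, timeline, templates)
    return config, timeline, templates


def _learning_p(p0: float, p_max: float, k: float, dose: int) -> float:
    return p0 + (p_max - p0) * (1.0 - math.exp(-k * dose))


_URGE_TARGETS = (
    (Behavior.binge, 0.6),
    (Behavior.vomiting, 0.2),
    (Behavior.fasting, 0.1),
    (Behavior.excessive_exercise, 0.1),
)


def simulate_patient(
    params: SimParams,
    config: Optional[PatientConfig] = None,
    goals_timeline: Optional[GoalsTimeline] = None,
    templates: Optional[dict[str, InterventionTemplate]] = None,
    start_date: dt.date = dt.date(2024, 1, 1),
) -> SimResult:
    """Simulate one patient's log, closed-loop with the decision engine.

    Every generated record passes entry validation; entries are emitted in
    time order and processed online through detect/gate/select so that skill
    use co-evolves with the interventions actually delivered. Intend-to-use
    responses are attached to every delivery.
    """
    if config is None or goals_timeline is None or templates is None:
        c, timeline, _ = pilot_goals_timeline(start_date, weeks=params.weeks)
        config = config if config is not None else c
        goals_timeline = goals_timeline if goals_timeline is not None else timeline
        templates = templates if templates is not None else default_templates()
    if goals_timeline.start is not None:
        start_date = min(start_date, goals_timeline.start)

    rng = np.random.default_rng(params.seed)
    p0, p_max, k = params.skill_learning
    state = EngineState()
    entries: list[EntryRecord] = []
    deliveries: list[DeliveredIntervention] = []
    latent_rows: list[dict] = []
    dropout_week: Optional[int] = None
    entry_counter = 0
    moods = np.array([1, 2, 3, 4, 5])

    def skill_p(skill: Skill) -> float:
        return _learning_p(p0, p_max, k, state.deliveries_by_skill.get(skill, 0))

    def process(entry: EntryRecord) -> None:
        nonlocal deliveries
        active = goals_timeline.active_goals(entry.timestamp.date())
        gated = gate_by_goals(detect_candidates(entry, state, config), active)
        delivery = select_intervention(
            gated, active, templates, state, config, now=entry.timestamp
        )
        advance_state(state, entry)
        if delivery is not None:
            if rng.random() < params.p_intend:
                delivery = record_response(delivery, True)
            else:
                reasons = list(DeclineReason)
                reason = reasons[int(rng.integers(0, len(reasons)))]
                delivery = record_response(delivery, False, reason)
            deliveries.append(delivery)

    def jitter_minutes() -> dt.timedelta:
        return dt.timedelta(minutes=float(rng.uniform(-20, 20)))

    for week in range(1, params.weeks + 1):
        p_log_week = params.p_log_entry * params.adherence_decay ** (week - 1)
        for day_idx in range(7):
            day = start_date + dt.timedelta(days=7 * (week - 1) + day_idx)
            latent_rows.append(
                {
                    "date": day,
                    "week": week,
                    **{
                        f"p_{s.value.lower()}": skill_p(s)
                        for s in (
                            Skill.URGE_MANAGEMENT,
                            Skill.MOOD_MANAGEMENT,
                            Skill.EAT_ENOUGH,
                        )
                    },
                    **{
                        f"n_{s.value.lower()}": state.deliveries_by_skill.get(s, 0)
                        for s in Skill
                    },
                }
            )
            if rng.random() < params.p_miss_day:
                continue
            day_entries: list[EntryRecord] = []
            for kind, slot_time in DEFAULT_MEAL_SLOTS:
                if rng.random() < params.p_skip_meal:
                    continue  # the episode never happens
                if rng.random() >= p_log_week:
                    continue  # happened but was not logged
                ts = dt.datetime.combine(day, slot_time) + jitter_minutes()
                mood = int(rng.choice(moods, p=params.mood_dist))
                urge = bool(rng.random() < params.p_urge_base)
                urge_target = None
                behaviors: set[Behavior] = set()
                loc = False
                if urge:
                    urge_target = _URGE_TARGETS[
                        rng.choice(len(_URGE_TARGETS), p=[w for _, w in _URGE_TARGETS])
                    ][0]
                    if rng.random() < params.p_behavior_given_urge:
                        behaviors.add(urge_target)
                        loc = urge_target is Behavior.binge
                entry_counter += 1
                day_entries.append(
                    EntryRecord(
                        entry_id=f"{config.patient_id}-e{entry_counter:05d}",
                        patient_id=config.patient_id,
                        timestamp=ts,
                        entry_kind=kind,
                        foods=(str(rng.choice(_SLOT_FOODS[kind])),),
                        loss_of_control=loc,
                        behaviors=frozenset(behaviors),
                        urge_present=urge,
                        urge_target=urge_target,
                        mood=mood,
                        used_mood_strategy=(
                            bool(rng.random() < skill_p(Skill.MOOD_MANAGEMENT))
                            if mood >= config.mood_trigger_threshold
                            else False
                        ),
                        used_urge_strategy=(
                            bool(rng.random() < skill_p(Skill.URGE_MANAGEMENT))
                            if urge
                            else None
                        ),
                        ate_enough=bool(rng.random() < skill_p(Skill.EAT_ENOUGH)),
                        ate_macro_range=bool(
                            rng.random() < skill_p(Skill.EAT_ENOUGH)
                        ),
                    )
                )
            if rng.random() < params.p_other_event * p_log_week / max(
                params.p_log_entry, 1e-9
            ):
                # an off-schedule urge / behavior / mood event that got logged
                hour = float(rng.uniform(9, 22.5))
                ts = dt.datetime.combine(day, dt.time(0, 0)) + dt.timedelta(hours=hour)
                event_kind = rng.choice(["urge", "behavior", "mood"], p=[0.5, 0.3, 0.2])
                mood = int(rng.choice(moods, p=params.mood_dist))
                urge = event_kind in ("urge", "behavior")
                urge_target = None
                behaviors = set()
                if urge:
                    urge_target = _URGE_TARGETS[
                        rng.choice(len(_URGE_TARGETS), p=[w for _, w in _URGE_TARGETS])
                    ][0]
                if event_kind == "behavior":
                    behaviors.add(urge_target)
                if event_kind == "mood":
                    mood = int(rng.choice([4, 5], p=[0.7, 0.3]))
                entry_counter += 1
                day_entries.append(
                    EntryRecord(
                        entry_id=f"{config.patient_id}-e{entry_counter:05d}",
                        patient_id=config.patient_id,
                        timestamp=ts,
                        entry_kind=EntryKind.other,
                        loss_of_control=Behavior.binge in behaviors,
                        behaviors=frozenset(behaviors),
                        urge_present=urge,
                        urge_target=urge_target,
                        mood=mood,
                        used_mood_strategy=(
                            bool(rng.random() < skill_p(Skill.MOOD_MANAGEMENT))
                            if mood >= config.mood_trigger_threshold
                            else False
                        ),
                        used_urge_strategy=(
                            bool(rng.random() < skill_p(Skill.URGE_MANAGEMENT))
                            if urge
                            else None
                        ),
                    )
                )
            for entry in sorted(day_entries, key=lambda e: e.timestamp):
                entries.append(entry)
                process(entry)
        if week < params.weeks and rng.random() < params.p_dropout_weekly:
            dropout_week = week + 1
            break

    return SimResult(
        entries=entries,
        deliveries=deliveries,
        latent=pd.DataFrame(latent_rows),
        start_date=start_date,
        dropout_week=dropout_week,
        params=params,
        config=config,
        goals_timeline=goals_timeline,
        templates=templates,
    )


def simulate_cohort(
    n: int,
    params: SimParams,
    seed: int,
    config: Optional[PatientConfig] = None,
    goals_timeline: Optional[GoalsTimeline] = None,
    templates: Optional[dict[str, InterventionTemplate]] = None,
    start_date: dt.date = dt.date(2024, 1, 1),
) -> list[SimResult]:
    """Simulate ``n`` independent patients with per-patient derived seeds."""
    if n < 1:
        raise SimulationError("cohort size must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    results = []
    for i, child in enumerate(child_seeds):
        p = params.model_copy(update={"seed": int(child)})
        cfg = (
            config.model_copy(update={"patient_id": f"p{i + 1:02d}"})
            if config is not None
            else None
        )
        results.append(
            simulate_patient(
                p, cfg, goals_timeline, templates, start_date=start_date
            )
        )
    return results


def recovery_scenario(
    seed: int, weeks: int = 16, true_params: tuple[float, float, float] = (0.2, 0.8, 0.05)
) -> SimResult:
    """One run of the learning-recovery scenario.

    Designed so the learning curve is identifiable: the urge-management goal
    is active throughout with no re-delivery gap, adherence decay/dropout are
    off (they only censor exposure and are irrelevant to the estimand), and
    urges are frequent (p=0.5 per entry) so that the cumulative dose
    saturates the curve (k*I of about 3, roughly 60+ deliveries) by the end
    of follow-up — the ceiling p_max is unidentifiable otherwise: the Fisher
    information bound at the default learning rate puts its best achievable
    error above 0.1 when the dose stalls below ~50.
    """
    start = dt.date(2024, 1, 1)
    templates = default_templates()
    config = PatientConfig(
        patient_id="recov",
        opened_skills={Skill.URGE_MANAGEMENT},
        per_skill_min_gap_h={Skill.URGE_MANAGEMENT: 0.0},
    )
    goal = PriorityGoal(
        goal_id="g-urge",
        skill=Skill.URGE_MANAGEMENT,
        description=_GOAL_DESCRIPTIONS[Skill.URGE_MANAGEMENT],
        linked_template_ids=("um-1", "um-2"),
    )
    timeline = GoalsTimeline(
        segments=(
            {
                "start": start,
                "end": start + dt.timedelta(days=7 * weeks),
                "goals": (goal,),
            },
        )
    )
    params = SimParams(
        weeks=weeks,
        p_urge_base=0.50,
        adherence_decay=1.0,
        p_dropout_weekly=0.0,
        skill_learning=true_params,
        seed=seed,
    )
    return simulate_patient(params, config, timeline, templates, start_date=start)


def learning_recovery_study(
    n_seeds: int = 50,
    weeks: int = 16,
    true_params: tuple[float, float, float] = (0.2, 0.8, 0.05),
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo recovery of the learning curve from simulated logs.

    Fits the pooled likelihood across the three skills that share one
    learning curve in the generator (urge management carries the moving dose;
    the zero-dose skills pin the baseline). Returns one row per replicate
    with the fitted (p0, p_max, k) and absolute errors against truth.
    """
    from .learning import SkillLearningModel

    child_seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    rows = []
    for child in child_seeds:
        sim = recovery_scenario(int(child), weeks=weeks, true_params=true_params)
        res = SkillLearningModel.from_log_pooled(sim.entries, sim.deliveries).fit()
        p0_hat, p_max_hat, k_hat = res.params
        rows.append(
            {
                "seed": int(child),
                "p0_hat": p0_hat,
                "p_max_hat": p_max_hat,
                "k_hat": k_hat,
                "abs_err_p0": abs(p0_hat - true_params[0]),
                "abs_err_p_max": abs(p_max_hat - true_params[1]),
                "n_obs": res.nobs,
            }
        )
    return pd.DataFrame(rows)
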