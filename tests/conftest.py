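import datetime as dt

import pytest
from hypothesis import settings

from skillnudge.models import (
    GoalSegment,
    GoalsTimeline,
    PatientConfig,
    PriorityGoal,
    Skill,
)
from skillnudge.simulate import default_templates

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")

START = dt.date(2024, 1, 1)


@pytest.fixture
def templates():
    return default_templates()


@pytest.fixture
def config():
    """All skills opened, default thresholds."""
    return PatientConfig(patient_id="pt", opened_skills=set(Skill))


def make_goal(skill: Skill, goal_id: str | None = None, template_ids=None):
    prefix = {
        Skill.REGULAR_EATING: "re",
        Skill.EAT_ENOUGH: "ee",
        Skill.FEARED_FOODS: "ff",
        Skill.URGE_MANAGEMENT: "um",
        Skill.TRIGGER_AWARENESS: "ta",
        Skill.MOOD_MANAGEMENT: "mm",
    }[skill]
    return PriorityGoal(
        goal_id=goal_id or f"g-{prefix}",
        skill=skill,
        linked_template_ids=tuple(template_ids or (f"{prefix}-1", f"{prefix}-2")),
    )


def make_timeline(*skills: Skill, start: dt.date = START, days: int = 365):
    goals = tuple(make_goal(s) for s in skills)
    return GoalsTimeline(
        segments=(
            GoalSegment(start=start, end=start + dt.timedelta(days=days), goals=goals),
        )
    )


def make_entry(**overrides):
    """A plain lunch entry at 2024-01-01 12:30; override freely."""
    from skillnudge.models import EntryKind, EntryRecord

    fields = dict(
        entry_id="e1",
        patient_id="pt",
        timestamp=dt.datetime(2024, 1, 1, 12, 30),
        entry_kind=EntryKind.lunch,
        mood=2,
    )
    fields.update(overrides)
    return EntryRecord(**fields)
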