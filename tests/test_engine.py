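"""Decision algorithm: detection rules, goal gating, single-winner selection."""

import datetime as dt

import pytest

from skillnudge.engine import (
    advance_state,
    detect_candidates,
    gate_by_goals,
    record_response,
    run_engine,
    select_intervention,
)
from skillnudge.errors import (
    ConfigurationError,
    ConsistencyError,
    OrderingError,
)
from skillnudge.models import (
    DeclineReason,
    EngineState,
    EntryKind,
    Skill,
    Trigger,
)

from conftest import make_entry, make_goal, make_timeline


def state_after_meal(at: dt.datetime) -> EngineState:
    s = EngineState()
    s.last_entry_time = at
    s.last_eating_episode_time = at
    return s


class TestDetect:
    def test_long_gap_without_eating_triggers_regular_eating(self, config):
        # lunch logged >5 waking hours after the 08:00 breakfast
        state = state_after_meal(dt.datetime(2024, 1, 1, 8, 0))
        entry = make_entry(timestamp=dt.datetime(2024, 1, 1, 13, 30))
        skills = {c.skill for c in detect_candidates(entry, state, config)}
        assert Skill.REGULAR_EATING in skills

    def test_short_gap_does_not_trigger(self, config):
        state = state_after_meal(dt.datetime(2024, 1, 1, 12, 0))
        entry = make_entry(timestamp=dt.datetime(2024, 1, 1, 13, 0))
        assert detect_candidates(entry, state, config) == []

    def test_overnight_hours_do_not_count_toward_gap(self, config):
        # 21:30 snack -> 09:00 breakfast is 11.5 wall hours but only
        # 1.5 + 1 = 2.5 waking hours with the 08:00-23:00 window
        state = state_after_meal(dt.datetime(2024, 1, 1, 21, 30))
        entry = make_entry(
            entry_kind=EntryKind.breakfast, timestamp=dt.datetime(2024, 1, 2, 9, 0)
        )
        assert detect_candidates(entry, state, config) == []

    def test_first_entry_cannot_fire_gap_rule(self, config):
        entry = make_entry(timestamp=dt.datetime(2024, 1, 1, 19, 0))
        assert detect_candidates(entry, EngineState(), config) == []

    def test_bad_mood_with_no_strategy_triggers_mood(self, config):
        entry = make_entry(mood=4, used_mood_strategy=False)
        skills = {c.skill for c in detect_candidates(entry, EngineState(), config)}
        assert skills == {Skill.MOOD_MANAGEMENT}

    @pytest.mark.parametrize(
        "mood,strategy", [(4, True), (4, None), (3, False), (2, None)]
    )
    def test_mood_rule_requires_threshold_and_explicit_no(self, config, mood, strategy):
        entry = make_entry(mood=mood, used_mood_strategy=strategy)
        skills = {c.skill for c in detect_candidates(entry, EngineState(), config)}
        assert Skill.MOOD_MANAGEMENT not in skills

    def test_unmanaged_urge_triggers_urge_and_awareness(self, config):
        entry = make_entry(urge_present=True, used_urge_strategy=False)
        skills = {c.skill for c in detect_candidates(entry, EngineState(), config)}
        assert skills == {Skill.URGE_MANAGEMENT, Skill.TRIGGER_AWARENESS}

    def test_managed_urge_still_prompts_trigger_awareness(self, config):
        entry = make_entry(urge_present=True, used_urge_strategy=True)
        skills = {c.skill for c in detect_candidates(entry, EngineState(), config)}
        assert skills == {Skill.TRIGGER_AWARENESS}

    def test_insufficient_meal_triggers_eat_enough(self, config):
        entry = make_entry(ate_enough=False, ate_macro_range=True)
        skills = {c.skill for c in detect_candidates(entry, EngineState(), config)}
        assert skills == {Skill.EAT_ENOUGH}

    def test_loc_episode_is_not_an_eat_enough_moment(self, config):
        entry = make_entry(
            ate_enough=False,
            loss_of_control=True,
            behaviors=frozenset({"binge"}),
        )
        skills = {c.skill for c in detect_candidates(entry, EngineState(), config)}
        assert Skill.EAT_ENOUGH not in skills

    def test_feared_food_declined_triggers_feared_foods(self, config):
        entry = make_entry(included_feared_food=False)
        skills = {c.skill for c in detect_candidates(entry, EngineState(), config)}
        assert skills == {Skill.FEARED_FOODS}

    def test_unopened_skills_are_never_candidates(self, config):
        closed = config.model_copy(update={"opened_skills": {Skill.REGULAR_EATING}})
        entry = make_entry(mood=5, used_mood_strategy=False, urge_present=True)
        assert detect_candidates(entry, EngineState(), closed) == []

    def test_out_of_order_entry_raises(self, config):
        state = state_after_meal(dt.datetime(2024, 1, 1, 12, 0))
        entry = make_entry(timestamp=dt.datetime(2024, 1, 1, 9, 0))
        with pytest.raises(OrderingError):
            detect_candidates(entry, state, config)


class TestGate:
    def test_candidate_without_goal_is_dropped(self, config):
        # an urge and a sad mood are both real opportunities, but only the
        # urge skill carries an active priority goal
        entry = make_entry(mood=4, used_mood_strategy=False, urge_present=True)
        cands = detect_candidates(entry, EngineState(), config)
        gated = gate_by_goals(cands, [make_goal(Skill.URGE_MANAGEMENT)])
        assert {c.skill for c in gated} == {Skill.URGE_MANAGEMENT}

    def test_empty_goal_set_gates_everything(self, config):
        entry = make_entry(mood=5, used_mood_strategy=False)
        cands = detect_candidates(entry, EngineState(), config)
        assert gate_by_goals(cands, []) == []

    def test_fully_covered_candidates_pass_unchanged(self, config):
        entry = make_entry(urge_present=True, used_urge_strategy=False)
        cands = detect_candidates(entry, EngineState(), config)
        goals = [make_goal(Skill.URGE_MANAGEMENT), make_goal(Skill.TRIGGER_AWARENESS)]
        assert gate_by_goals(cands, goals) == cands


class TestSelect:
    def test_single_candidate_delivers_its_template(self, config, templates):
        entry = make_entry(urge_present=True, used_urge_strategy=False)
        goals = [make_goal(Skill.URGE_MANAGEMENT)]
        state = EngineState()
        gated = gate_by_goals(detect_candidates(entry, state, config), goals)
        d = select_intervention(gated, goals, templates, state, config, entry.timestamp)
        assert d is not None
        assert d.trigger is Trigger.urge
        assert d.template_id in ("um-1", "um-2")
        assert d.goal_id == "g-um"

    def test_empty_gated_list_changes_nothing(self, config, templates):
        state = EngineState()
        d = select_intervention(
            [], [], templates, state, config, dt.datetime(2024, 1, 1, 12)
        )
        assert d is None and state.total_deliveries == 0

    def test_two_templates_alternate_round_robin(self, config, templates):
        # two successive urge triggers must use um-1 then um-2 then um-1
        goals = [make_goal(Skill.URGE_MANAGEMENT)]
        state = EngineState()
        seen = []
        for hour in (9, 12, 15):
            entry = make_entry(
                entry_id=f"e{hour}",
                timestamp=dt.datetime(2024, 1, 1, hour),
                urge_present=True,
                used_urge_strategy=False,
            )
            gated = gate_by_goals(detect_candidates(entry, state, config), goals)
            d = select_intervention(
                gated, goals, templates, state, config, entry.timestamp
            )
            advance_state(state, entry)
            seen.append(d.template_id)
        assert seen == ["um-1", "um-2", "um-1"]

    def test_goal_priority_order_beats_skill_precedence(self, config, templates):
        # clinician ranks the urge goal above regular eating
        goals = [make_goal(Skill.REGULAR_EATING), make_goal(Skill.URGE_MANAGEMENT)]
        cfg = config.model_copy(update={"goal_priority_order": ("g-um", "g-re")})
        state = state_after_meal(dt.datetime(2024, 1, 1, 8))
        entry = make_entry(
            timestamp=dt.datetime(2024, 1, 1, 14),
            urge_present=True,
            used_urge_strategy=False,
        )
        gated = gate_by_goals(detect_candidates(entry, state, cfg), goals)
        d = select_intervention(gated, goals, templates, state, cfg, entry.timestamp)
        assert d.skill is Skill.URGE_MANAGEMENT

    def test_precedence_breaks_ties_without_clinician_order(self, config, templates):
        goals = [make_goal(Skill.MOOD_MANAGEMENT), make_goal(Skill.EAT_ENOUGH)]
        entry = make_entry(
            mood=5, used_mood_strategy=False, ate_enough=False
        )
        state = EngineState()
        gated = gate_by_goals(detect_candidates(entry, state, config), goals)
        d = select_intervention(gated, goals, templates, state, config, entry.timestamp)
        assert d.skill is Skill.EAT_ENOUGH  # restraint skill wins the tie

    def test_min_gap_suppresses_repeat_delivery(self, config, templates):
        cfg = config.model_copy(
            update={"per_skill_min_gap_h": {Skill.URGE_MANAGEMENT: 6.0}}
        )
        goals = [make_goal(Skill.URGE_MANAGEMENT)]
        state = EngineState()
        out = []
        for hour in (9, 12, 16):
            entry = make_entry(
                entry_id=f"e{hour}",
                timestamp=dt.datetime(2024, 1, 1, hour),
                urge_present=True,
                used_urge_strategy=False,
            )
            gated = gate_by_goals(detect_candidates(entry, state, cfg), goals)
            out.append(
                select_intervention(gated, goals, templates, state, cfg, entry.timestamp)
            )
            advance_state(state, entry)
        assert [d is not None for d in out] == [True, False, True]

    def test_goal_without_templates_is_configuration_error(self, config, templates):
        goal = make_goal(Skill.URGE_MANAGEMENT).model_copy(
            update={"linked_template_ids": ()}
        )
        entry = make_entry(urge_present=True, used_urge_strategy=False)
        state = EngineState()
        gated = gate_by_goals(detect_candidates(entry, state, config), [goal])
        with pytest.raises(ConfigurationError):
            select_intervention(gated, [goal], templates, state, config, entry.timestamp)


class TestRecordResponse:
    def _delivery(self, config, templates):
        entry = make_entry(urge_present=True, used_urge_strategy=False)
        goals = [make_goal(Skill.URGE_MANAGEMENT)]
        state = EngineState()
        gated = gate_by_goals(detect_candidates(entry, state, config), goals)
        return select_intervention(gated, goals, templates, state, config, entry.timestamp)

    def test_accepting_stores_no_reason(self, config, templates):
        d = record_response(self._delivery(config, templates), True)
        assert d.intends_to_use is True and d.decline_reason is None

    def test_declining_stores_reason(self, config, templates):
        d = record_response(self._delivery(config, templates), False, "too_hard")
        assert d.decline_reason is DeclineReason.too_hard

    def test_decline_without_reason_is_inconsistent(self, config, templates):
        with pytest.raises(ConsistencyError):
            record_response(self._delivery(config, templates), False)

    def test_reason_with_acceptance_is_inconsistent(self, config, templates):
        with pytest.raises(ConsistencyError):
            record_response(self._delivery(config, templates), True, "too_hard")

    def test_double_response_rejected(self, config, templates):
        d = record_response(self._delivery(config, templates), True)
        with pytest.raises(ConsistencyError):
            record_response(d, False, "not_relevant")


class TestRunEngine:
    def test_empty_log_yields_no_deliveries(self, config, templates):
        deliveries, state = run_engine([], config, make_timeline(), templates)
        assert deliveries == [] and state.total_deliveries == 0

    def test_gap_scenario_delivers_exactly_one_regular_eating(self, config, templates):
        # breakfast, then a snack >5 waking hours later, regular-eating goal active
        timeline = make_timeline(Skill.REGULAR_EATING)
        log = [
            make_entry(
                entry_id="b",
                entry_kind=EntryKind.breakfast,
                timestamp=dt.datetime(2024, 1, 1, 8, 0),
            ),
            make_entry(
                entry_id="s",
                entry_kind=EntryKind.midafternoon_snack,
                timestamp=dt.datetime(2024, 1, 1, 13, 30),
            ),
        ]
        deliveries, _ = run_engine(log, config, timeline, templates)
        assert len(deliveries) == 1
        assert deliveries[0].trigger is Trigger.regular_eating_gap
        assert deliveries[0].source_entry_id == "s"

    def test_mood_scenario_delivers_exactly_one_mood(self, config, templates):
        timeline = make_timeline(Skill.MOOD_MANAGEMENT)
        log = [make_entry(mood=4, used_mood_strategy=False)]
        deliveries, _ = run_engine(log, config, timeline, templates)
        assert [d.trigger for d in deliveries] == [Trigger.mood]

    def test_sadness_without_mood_goal_is_ignored(self, config, templates):
        # urge goal active, mood goal not: the urge fires, the sadness does not
        timeline = make_timeline(Skill.URGE_MANAGEMENT)
        log = [
            make_entry(
                mood=4, used_mood_strategy=False, urge_present=True,
                used_urge_strategy=False,
            )
        ]
        deliveries, _ = run_engine(log, config, timeline, templates)
        assert [d.trigger for d in deliveries] == [Trigger.urge]

    def test_batch_replay_is_deterministic(self, config, templates):
        import numpy as np
        import sys, pathlib

        sys.path.insert(0, str(pathlib.Path(__file__).parent))
        from _oracle import random_scenario

        log, cfg, timeline, tpls = random_scenario(np.random.default_rng(7))
        a, _ = run_engine(log, cfg, timeline, tpls)
        b, _ = run_engine(log, cfg, timeline, tpls)
        assert a == b
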