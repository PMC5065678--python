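from __future__ import annotations

import itertools
import random
from datetime import datetime, timedelta

import pytest

from alarmaudit.chain import (DISPLAY_CAP, MonitorState, announce,
                              apply_user_action, end_condition, make_active,
                              raise_alarm, run_scenario, severity_rank)
from alarmaudit.grammar import SoundEvent, parse_message
from alarmaudit.parsing import parse_records

from .oracles import brute_force_announced

T0 = datetime(2014, 4, 20, 12, 0, 0)


def at(seconds: float) -> datetime:
    return T0 + timedelta(seconds=seconds)


def _active(msg, alarm_id, onset=T0):
    return make_active(parse_message(msg), onset_ts=onset, alarm_id=alarm_id)


class TestWorkedExamples:
    def test_pause_suppressed_by_active_paired_pvcs(self):
        """Pause (short yellow) stays silent while Pair PVCs (long
        yellow) is active; alone, Pause announces."""
        pause = _active("**Pause Generated.", 1, at(0))
        pair = _active("**Pair PVCs Generated.", 2, at(5))
        result = announce([pause, pair], now=at(6))
        assert result.announced == [pair]
        suppressed = {id(a): reason for a, reason in result.suppressed}
        assert id(pause) in suppressed
        assert "long yellow" in suppressed[id(pause)]
        alone = announce([pause], now=at(6))
        assert alone.announced == [pause]

    def test_twelve_concurrent_alarms_display_ten(self):
        msgs = (["***Desat %d < 88 Generated." % v for v in (70, 71)]
                + ["**HR 1%d0 >120 Generated." % d for d in range(4)]
                + ["**RR 3%d >30 Generated." % d for d in range(3)]
                + ["*Multiform PVCs Generated.",
                   "ECG Leads Off Generated.",
                   "!!Check Equipment Generated."])
        assert len(msgs) == 12
        active = [_active(m, i, at(i)) for i, m in enumerate(msgs)]
        result = announce(active, now=at(20))
        assert len(result.display_list) == DISPLAY_CAP == 10
        # display is ordered by severity, then recency
        ranks = [severity_rank(a) for a in result.display_list]
        assert ranks == sorted(ranks, reverse=True)

    def test_red_beats_yellow_in_same_chain(self):
        vtach = _active("***VTach Generated.", 1, at(0))
        pair = _active("**Pair PVCs Generated.", 2, at(3))
        result = announce([vtach, pair], now=at(4))
        assert result.announced == [vtach]

    def test_independent_parameters_announce_concurrently(self):
        desat = _active("***Desat 70 < 88 Generated.", 1, at(0))
        asys = _active("***Asystole Generated.", 2, at(1))
        result = announce([desat, asys], now=at(2))
        assert set(a.alarm_id for a in result.announced) == {1, 2}

    def test_equal_severity_most_recent_is_primary(self):
        older = _active("***Desat 70 < 88 Generated.", 1, at(0))
        newer = _active("***Asystole Generated.", 2, at(8))
        result = announce([older, newer], now=at(9))
        assert result.primary is newer

    def test_soft_inop_displays_without_announcing(self):
        leads = _active("ECG Leads Off Generated.", 1, at(0))
        result = announce([leads], now=at(1))
        assert result.announced == []
        assert leads in result.display_list


class TestSuppressionMonotonicity:
    def test_adding_alarms_never_unsuppresses(self):
        """If an alarm is not announced in a set, it stays silent in
        every superset (adding alarms only adds competition)."""
        pool = [_active(m, i, at(i)) for i, m in enumerate([
            "***VTach Generated.", "**Pair PVCs Generated.",
            "**Pause Generated.", "**HR 130 >120 Generated.",
            "*Multiform PVCs Generated."])]
        full_ann = {a.alarm_id for a in announce(pool, now=at(60)).announced}
        for k in range(1, len(pool)):
            for subset in itertools.combinations(pool, k):
                sub_ann = {a.alarm_id
                           for a in announce(list(subset), now=at(60)).announced}
                for alarm in subset:
                    if alarm.alarm_id not in sub_ann:
                        assert alarm.alarm_id not in full_ann

    def test_announce_is_deterministic_under_input_order(self):
        pool = [_active(m, i, at(i % 3)) for i, m in enumerate([
            "***Desat 70 < 88 Generated.", "**HR 130 >120 Generated.",
            "**Pause Generated.", "**Pair PVCs Generated.",
            "ECG Leads Off Generated."])]
        baseline = announce(pool, now=at(10))
        rng = random.Random(1)
        for _ in range(10):
            shuffled = pool[:]
            rng.shuffle(shuffled)
            got = announce(shuffled, now=at(10))
            assert [a.alarm_id for a in got.announced] == \
                [a.alarm_id for a in baseline.announced]
            assert [a.alarm_id for a in got.display_list] == \
                [a.alarm_id for a in baseline.display_list]


def test_announced_set_matches_declarative_oracle():
    """On hundreds of random alarm sets of up to 6 alarms the announced
    set equals a rule-by-rule declarative filter."""
    msgs = ["***VTach Generated.", "***Asystole Generated.",
            "***Desat 70 < 88 Generated.", "**Pair PVCs Generated.",
            "**Pause Generated.", "**HR 130 >120 Generated.",
            "**Missed Beat Generated.", "*Multiform PVCs Generated.",
            "ECG Leads Off Generated.", "!!Check Equipment Generated."]
    rng = random.Random(7)
    for trial in range(300):
        chosen = rng.sample(msgs, rng.randrange(0, 7))
        active = [_active(m, i, at(rng.randrange(0, 30)))
                  for i, m in enumerate(chosen)]
        got = {a.alarm_id for a in announce(active, now=at(60)).announced}
        want = brute_force_announced(active)
        assert got == want, chosen


class TestMonitorState:
    def test_pause_silences_then_resume_restores(self):
        state = MonitorState()
        raise_alarm(state, parse_message("**HR 130 >120 Generated."), at(0))
        assert state.announce(at(1)).announced
        apply_user_action(state, parse_message("Pause All Alarms."), at(2),
                          pause_minutes=2)
        assert state.announce(at(3)).announced == []
        # pause expires after 2 minutes
        assert state.announce(at(125)).announced
        apply_user_action(state, parse_message("Pause All Alarms."), at(130),
                          pause_minutes=None)  # infinite
        assert state.announce(at(10_000)).announced == []
        apply_user_action(state, parse_message("Resume All Alarms."),
                          at(10_001))
        assert state.announce(at(10_002)).announced

    def test_yellow_only_pause_leaves_reds_audible(self):
        state = MonitorState(yellow_only_pause=True)
        raise_alarm(state, parse_message("**HR 130 >120 Generated."), at(0))
        red = raise_alarm(state, parse_message("***Desat 70 < 88 Generated."),
                          at(0))
        apply_user_action(state, parse_message("Pause All Alarms."), at(1),
                          pause_minutes=2)
        announced = state.announce(at(2)).announced
        assert [a.alarm_id for a in announced] == [red.alarm_id]

    def test_latching_red_persists_until_silenced(self):
        """Asystole keeps announcing after the rhythm recovers and only
        clears on an explicit Silence."""
        state = MonitorState()
        asys = raise_alarm(state, parse_message("***Asystole Generated."),
                           at(0))
        assert asys.latching
        end_condition(state, asys, at(10))
        assert [a.alarm_id for a in state.announce(at(11)).announced] \
            == [asys.alarm_id]
        apply_user_action(state, parse_message("Silence."), at(12))
        assert state.announce(at(13)).announced == []

    def test_nonlatching_alarm_clears_when_condition_ends(self):
        state = MonitorState()
        hr = raise_alarm(state, parse_message("**HR 130 >120 Generated."),
                         at(0))
        assert not hr.latching
        end_condition(state, hr, at(5))
        assert state.announce(at(6)).announced == []
        assert state.active == []

    def test_silence_keeps_ongoing_condition_on_screen(self):
        state = MonitorState()
        hr = raise_alarm(state, parse_message("**HR 130 >120 Generated."),
                         at(0))
        apply_user_action(state, parse_message("Silence."), at(1))
        result = state.announce(at(2))
        assert result.announced == []
        assert [a.alarm_id for a in result.silent_display] == [hr.alarm_id]

    def test_unsupported_action_rejected(self):
        state = MonitorState()
        with pytest.raises(ValueError, match="action kind"):
            apply_user_action(
                state, parse_message("Patient transferred to 9035-S1."),
                at(0))


class TestRunScenario:
    def test_scenario_rows_round_trip_through_parser(self):
        steps = [
            {"t": at(0), "raise": "**HR 130 >120 Generated."},
            {"t": at(5), "raise": "***Desat 70 < 88 Generated."},
            {"t": at(20), "action": "Silence."},
            {"t": at(40), "end": "**HR 130 >120 Generated."},
            {"t": at(60), "end": "***Desat 70 < 88 Generated."},
        ]
        records, results = run_scenario(steps, bed_label="9001-S1")
        parsed = parse_records(records, strict=True)
        kinds = [p.event.kind for p in parsed
                 if isinstance(p.event, SoundEvent)]
        assert "yellow" in kinds and "red" in kinds
        msgs = [p.record.raw_message for p in parsed]
        assert "**HR 130 >120 Generated." in msgs
        assert "Silence." in msgs
        assert results[-1].announced == []

    def test_sound_rows_only_on_new_announcements(self):
        steps = [
            {"t": at(0), "raise": "**Pair PVCs Generated."},
            {"t": at(2), "raise": "**Pause Generated."},
            {"t": at(30), "end": "**Pair PVCs Generated."},
            {"t": at(31), "end": "**Pause Generated."},
        ]
        records, _ = run_scenario(steps)
        yellow_sounds = [r for r in records
                         if r.raw_message == "Yellow alarm sound played."]
        # Pair PVCs announces at t=0; the suppressed Pause adds no sound
        # until Pair PVCs ends, when Pause takes over (one more sound).
        assert len(yellow_sounds) == 2
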