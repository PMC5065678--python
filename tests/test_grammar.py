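from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alarmaudit.grammar import (AlarmPriority, PhysiologicAlarm, SoundEvent,
                                TechnicalAlarm, UnparsedEvent, UserAction,
                                parse_limit_change, parse_message,
                                render_event)

NUMERICAL_CASES = [
    # message, stars, color, param, value, limit, direction, status
    ("**PAPd 18 >16 Generated.", 2, "yellow", "PAPd", 18, 16, "above", "generated"),
    ("**PAPd 18 >16 Ended.", 2, "yellow", "PAPd", 18, 16, "above", "ended"),
    ("**ABPs 170 >160 Generated.", 2, "yellow", "ABPs", 170, 160, "above", "generated"),
    ("**ABPs 168 >160 Ended.", 2, "yellow", "ABPs", 168, 160, "above", "ended"),
    ("***Desat 70 < 78 Generated.", 3, "red", "Desat", 70, 78, "below", "generated"),
    ("***Desat 73 < 78 ended.", 3, "red", "Desat", 73, 78, "below", "ended"),
    ("**RR 37 >30 Ended.", 2, "yellow", "RR", 37, 30, "above", "ended"),
    ("*** Desat 89 < 90 Generated.", 3, "red", "Desat", 89, 90, "below", "generated"),
    ("*** Desat 87 < 88 Generated.", 3, "red", "Desat", 87, 88, "below", "generated"),
    ("*** Desat 8 < 80 Generated.", 3, "red", "Desat", 8, 80, "below", "generated"),
    ("*** Desat 44 < 50 Generated.", 3, "red", "Desat", 44, 50, "below", "generated"),
    ("*** Desat 80 < 83 Generated.", 3, "red", "Desat", 80, 83, "below", "generated"),
    ("*** Desat 0 < 78 Generated.", 3, "red", "Desat", 0, 78, "below", "generated"),
    ("*HR 153>150 Generated.", 1, "advisory", "HR", 153, 150, "above", "generated"),
    ("**HR 153 >150 Generated.", 2, "yellow", "HR", 153, 150, "above", "generated"),
]


@pytest.mark.parametrize(
    "msg, level, color, param, value, limit, direction, status",
    NUMERICAL_CASES)
def test_numerical_alarm_messages(msg, level, color, param, value, limit,
                                  direction, status):
    """Numerical messages yield priority, parameter, value, limit,
    direction and status exactly as printed, with flexible whitespace
    around the comparator and case-insensitive status."""
    ev = parse_message(msg)
    assert isinstance(ev, PhysiologicAlarm)
    assert ev.priority.level == level
    assert ev.priority.color == color
    assert ev.parameter == param
    assert ev.measurement_kind == "numerical"
    assert ev.trigger_value == value
    assert ev.limit_value == limit
    assert ev.direction == direction
    assert ev.status == status


def test_categorical_physiologic_alarm():
    ev = parse_message("*Multiform PVCs Generated.")
    assert isinstance(ev, PhysiologicAlarm)
    assert ev.priority.level == 1 and ev.priority.color == "advisory"
    assert ev.measurement_kind == "categorical"
    assert ev.trigger_value is None and ev.limit_value is None
    assert ev.direction == "none"


def test_soft_inop_has_no_priority_mark():
    ev = parse_message("ECG Leads Off Generated.")
    assert isinstance(ev, TechnicalAlarm)
    assert ev.priority.level == 0 and ev.priority.family == "technical"
    assert ev.priority.color == "none"
    assert ev.name == "ECG Leads Off"
    assert ev.status == "generated"


@pytest.mark.parametrize("msg, level", [
    ("!Batt Empty Generated.", 1),
    ("!!Batt Empty Generated.", 2),
    ("!!!Check Equipment Generated.", 3),
])
def test_marked_inop_levels(msg, level):
    ev = parse_message(msg)
    assert isinstance(ev, TechnicalAlarm)
    assert ev.priority.level == level and ev.priority.family == "technical"


@pytest.mark.parametrize("msg, kind", [
    ("Red alarm sound played.", "red"),
    ("Yellow alarm sound played.", "yellow"),
    ("INOP sound played.", "inop"),
])
def test_sound_events(msg, kind):
    ev = parse_message(msg)
    assert isinstance(ev, SoundEvent) and ev.kind == kind


@pytest.mark.parametrize("msg, kind", [
    ("Silence.", "Silence"),
    ("Pause All Alarms.", "Pause Alarms"),
    ("Resume All Alarms.", "Resume Alarms"),
    ("Patient transferred to 9035-S1.", "Transfer"),
    ("Patient category set to Adult.", "Patient Category Changed"),
    ("Pacer algorithm set to Pacer Algorithm On.", "Paced Status Changed"),
    ("Equipment Offline.", "Equipment Offline"),
    ("Equipment Online.", "Equipment Online"),
    ("Arrhythmia Off.", "Measurement Off"),
    ("Arrhy: Missed Beat Off.", "Alarm Off"),
])
def test_user_actions(msg, kind):
    ev = parse_message(msg)
    assert isinstance(ev, UserAction) and ev.action_kind == kind


class TestApneaForms:
    """Apnea appears in three message forms: a plain categorical
    generation, a minutes:seconds duration, and an over-20-seconds
    overflow message."""

    def test_plain_generated_is_categorical(self):
        ev = parse_message("***Apnea Generated.")
        assert ev.measurement_kind == "categorical"
        assert ev.apnea_detail is None

    def test_clock_duration_in_seconds(self):
        ev = parse_message("***Apnea 0:25 Generated.")
        assert ev.measurement_kind == "numerical"
        assert ev.apnea_detail == 25.0
        assert ev.limit_value is None  # no comparator in this display

    def test_clock_duration_with_minutes(self):
        ev = parse_message("***Apnea 1:05 Generated.")
        assert ev.apnea_detail == 65.0

    def test_over_20_seconds_flag(self):
        ev = parse_message("***Apnea > 20 sec Generated.")
        assert ev.apnea_over_20s is True
        assert ev.apnea_detail == 20.0


class TestLimitChanges:
    def test_single_bound_uses_registry_side(self):
        ev = parse_limit_change("SpO_2_: Desat Limit 78.")
        assert isinstance(ev, UserAction)
        assert ev.action_kind == "Alarm Limit Change"
        (change,) = ev.limit_changes
        assert change.parameter == "Desat"
        assert change.lower == 78.0 and change.upper is None

    def test_high_low_pair_preserves_sign(self):
        ev = parse_limit_change("ST: Al. Limits ST-V2 High: 1.6 ST-V2 Low: −1.6.")
        (change,) = ev.limit_changes
        assert change.parameter == "ST-V2"
        assert change.upper == 1.6 and change.lower == -1.6

    def test_alarm_off_form_has_no_bounds(self):
        ev = parse_limit_change("Arrhy: Missed Beat Off.")
        assert isinstance(ev, UserAction)
        assert ev.action_kind == "Alarm Off"
        assert ev.limit_changes == ()

    def test_settings_form_without_bound_is_unparsed(self):
        ev = parse_limit_change("SpO2: Desat Limit high.")
        assert isinstance(ev, UnparsedEvent)


def test_every_sample_message_parses(unit_log_parsed, desat_parsed,
                                     hr_pair_parsed):
    """Total function over the bundled exhibits: no message is dropped
    or left unparsed."""
    for parsed in (unit_log_parsed, desat_parsed, hr_pair_parsed):
        assert not any(isinstance(p.event, UnparsedEvent) for p in parsed)


def test_unknown_text_is_carried_not_dropped():
    ev = parse_message("Completely novel gibberish 123")
    assert isinstance(ev, UnparsedEvent)
    assert "gibberish" in ev.raw


def test_unknown_parameter_parses_generically():
    ev = parse_message("**XyzNew 42 >40 Generated.")
    assert isinstance(ev, PhysiologicAlarm)
    assert ev.parameter == "XyzNew" and ev.limit_value == 40.0


def test_subscript_spellings_normalize():
    a = parse_message("**SpO2 85 < 90 Generated.")
    b = parse_message("**SpO_2 85 < 90 Generated.")
    assert a.parameter == b.parameter == "SpO2"


def test_classification_exclusivity(unit_log_parsed):
    """No alarm is both numerical and categorical; numerical comparator
    alarms carry value, limit and direction, categorical carry none."""
    for p in unit_log_parsed:
        ev = p.event
        if not isinstance(ev, PhysiologicAlarm):
            continue
        if ev.measurement_kind == "numerical" and ev.apnea_detail is None:
            assert ev.trigger_value is not None
            assert ev.limit_value is not None
            assert ev.direction in ("above", "below")
        if ev.measurement_kind == "categorical":
            assert ev.trigger_value is None
            assert ev.limit_value is None
            assert ev.direction == "none"


_PARAMS = st.sampled_from(["HR", "RR", "Desat", "ABPs", "PAPd", "SpO2"])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(level=st.integers(1, 3), param=_PARAMS,
       value=st.integers(0, 300), limit=st.integers(1, 299),
       above=st.booleans(), ended=st.booleans())
def test_priority_star_bijection(level, param, value, limit, above, ended):
    """Rendering a parsed physiologic alarm reproduces the original
    star count, and re-parsing the rendering is the identity."""
    marks = "*" * level
    cmp_ = ">" if above else "<"
    status = "Ended" if ended else "Generated"
    msg = f"{marks}{param} {value} {cmp_}{limit} {status}."
    ev = parse_message(msg)
    assert isinstance(ev, PhysiologicAlarm)
    rendered = render_event(ev)
    assert rendered.count("*") == level
    assert parse_message(rendered) == ev
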