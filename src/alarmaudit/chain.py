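"""Simulate how the monitor announces concurrent alarms.

Not every detected alarm is heard.  The monitor resolves concurrent
alarms with a priority algorithm built on three chains — PVC alarms,
beat detection, and rate alarms — and only the highest-priority active
condition in each chain is announced.  Announcement severity runs:
unacknowledged red alarms first, then long yellow alarms (in the
presence of any other yellow or INOP), then short yellow, then hard
INOP technical alarms, then soft INOPs (which make no sound at all).
When two chains tie in severity the more recent alarm is announced.
The active-alarm drop-down shows at most 10 alarms.  Silencing turns
the audio off while the condition persists (the message stays on
screen); latching alarms — high-priority red conditions such as
asystole — keep sounding even after the condition ends, until a
clinician silences them.

This matters for analytics: an audit log records every detected alarm,
but clinicians only ever experienced the announced subset, and
observation studies miss the suppressed remainder entirely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence, Union

from .grammar import (AlarmPriority, PhysiologicAlarm, SoundEvent,
                      TechnicalAlarm, UserAction, parse_message, render_event)
from .records import AuditRecord
from .registry import DEFAULT_REGISTRY, Registry

__all__ = ["ActiveAlarm", "AnnouncementResult", "announce", "MonitorState",
           "apply_user_action", "end_condition", "raise_alarm",
           "run_scenario", "DISPLAY_CAP", "severity_rank"]

DISPLAY_CAP = 10

# Announcement severity classes, highest first.  Advisory physiologic
# alarms and single-mark INOPs are not placed explicitly by the vendor's
# stated ordering; they slot between short yellow and the INOP tiers in
# mark-count order (a documented choice, overridable nowhere — it only
# affects ties the stated ordering leaves open).
_RANK = {
    "red": 60,
    "long_yellow": 50,
    "short_yellow": 40,
    "advisory": 30,
    "hard_inop": 20,
    "moderate_inop": 15,
    "low_inop": 12,
    "soft_inop": 10,
}


@dataclass
class ActiveAlarm:
    """One alarm condition currently tracked by the simulator."""

    alarm_id: int
    event: Union[PhysiologicAlarm, TechnicalAlarm]
    chain: str  # "pvc" | "beat_detection" | "rate" | "none"
    onset_ts: datetime
    latching: bool = False
    yellow_class: str = "short"  # announcement class for yellow alarms
    acknowledged: bool = False
    condition_active: bool = True

    def __post_init__(self) -> None:
        # latching is a property of continuous-tone red alarms only
        if self.latching and not (
                isinstance(self.event, PhysiologicAlarm)
                and self.event.priority.level == 3):
            raise ValueError("only high-priority (***) physiologic alarms "
                             "can latch")

    @property
    def severity_class(self) -> str:
        pr = self.event.priority
        if pr.family == "physiologic":
            if pr.level == 3:
                return "red"
            if pr.level == 2:
                return f"{self.yellow_class}_yellow"
            return "advisory"
        return {3: "hard_inop", 2: "moderate_inop",
                1: "low_inop", 0: "soft_inop"}[pr.level]

    @property
    def audible_class(self) -> bool:
        return self.severity_class != "soft_inop"

    @property
    def parameter(self) -> str:
        return self.event.parameter


def severity_rank(alarm: ActiveAlarm) -> int:
    return _RANK[alarm.severity_class]


def make_active(event: Union[PhysiologicAlarm, TechnicalAlarm],
                onset_ts: datetime, alarm_id: int,
                registry: Registry = DEFAULT_REGISTRY) -> ActiveAlarm:
    """Build an ActiveAlarm with chain/latching/class from the registry."""
    info = registry.lookup(event.parameter)
    latching = (info.latching and isinstance(event, PhysiologicAlarm)
                and event.priority.level == 3)
    return ActiveAlarm(alarm_id=alarm_id, event=event, chain=info.chain,
                       onset_ts=onset_ts, latching=latching,
                       yellow_class=info.yellow_class)


@dataclass
class AnnouncementResult:
    announced: list[ActiveAlarm]  # at most one per chain, audibly active
    primary: Optional[ActiveAlarm]  # the single most recent top alarm
    display_list: list[ActiveAlarm]  # <= DISPLAY_CAP, severity then recency
    silent_display: list[ActiveAlarm]  # silenced but persisting: shown, no sound
    suppressed: list[tuple[ActiveAlarm, str]]  # (alarm, reason)


def _is_live(a: ActiveAlarm) -> bool:
    """Still demanding attention: condition present, or latched unsilenced."""
    return a.condition_active or (a.latching and not a.acknowledged)


def announce(active: Sequence[ActiveAlarm],
             now: Optional[datetime] = None) -> AnnouncementResult:
    """Resolve which of the active alarms are announced right now.

    Pure function of the active set: identical input gives identical
    output.  ``now`` is accepted for interface symmetry; recency is
    judged from onset timestamps.
    """
    live = [a for a in active if _is_live(a)]
    by_recency = sorted(live, key=lambda a: (-severity_rank(a), a.onset_ts),
                        reverse=False)
    # display: severity desc, then most recent first within a class
    display_sorted = sorted(
        live, key=lambda a: (-severity_rank(a),
                             -a.onset_ts.timestamp(), -a.alarm_id))
    display_list = display_sorted[:DISPLAY_CAP]

    suppressed: list[tuple[ActiveAlarm, str]] = []
    silent_display = [a for a in live if a.acknowledged]
    # soft INOPs are displayed but never make a sound
    candidates = [a for a in live if not a.acknowledged and a.audible_class]
    for a in silent_display:
        suppressed.append((a, "silenced: message displayed without sound"))

    if not candidates:
        return AnnouncementResult([], None, display_list, silent_display,
                                  suppressed)

    top = max(severity_rank(a) for a in candidates)
    winners: list[ActiveAlarm] = []
    chain_key = lambda a: (a.chain if a.chain != "none"
                           else f"none:{a.alarm_id}")
    for _, members in itertools.groupby(
            sorted(candidates, key=chain_key), key=chain_key):
        members = list(members)
        best = max(members, key=lambda a: (severity_rank(a),
                                           a.onset_ts, a.alarm_id))
        for a in members:
            if a is not best:
                suppressed.append(
                    (a, f"outranked in {a.chain} chain by {best.parameter}"))
        if severity_rank(best) == top:
            winners.append(best)
        else:
            suppressed.append(
                (best, f"lower priority than an active "
                       f"{_top_name(candidates, top)} alarm"))
    primary = max(winners, key=lambda a: (a.onset_ts, a.alarm_id),
                  default=None)
    winners.sort(key=lambda a: (-a.onset_ts.timestamp(), -a.alarm_id))
    return AnnouncementResult(winners, primary, display_list, silent_display,
                              suppressed)


def _top_name(candidates: Sequence[ActiveAlarm], top: int) -> str:
    best = max(candidates, key=severity_rank)
    return best.severity_class.replace("_", " ")


@dataclass
class MonitorState:
    """Mutable simulator state for one bed's alarm behavior."""

    registry: Registry = field(default_factory=lambda: DEFAULT_REGISTRY)
    active: list[ActiveAlarm] = field(default_factory=list)
    pause_until: Optional[datetime] = None  # None = not paused
    pause_infinite: bool = False
    yellow_only_pause: bool = False  # "All Alarms Off for Yellow Alarms Only"
    _next_id: int = 0

    def paused_for(self, alarm: ActiveAlarm, now: datetime) -> bool:
        if not self.pause_infinite and (self.pause_until is None
                                        or now >= self.pause_until):
            return False
        if self.yellow_only_pause:
            pr = alarm.event.priority
            return not (pr.family == "physiologic" and pr.level == 3)
        return True

    def announce(self, now: datetime) -> AnnouncementResult:
        audible = [a for a in self.active if not self.paused_for(a, now)]
        return announce(audible, now)


def raise_alarm(state: MonitorState,
                event: Union[PhysiologicAlarm, TechnicalAlarm],
                now: datetime) -> ActiveAlarm:
    alarm = make_active(event, now, state._next_id, state.registry)
    state._next_id += 1
    state.active.append(alarm)
    return alarm


def end_condition(state: MonitorState, alarm: ActiveAlarm,
                  now: datetime) -> None:
    """The physiologic condition resolved.

    Nonlatching alarms reset their indicators and leave the active set;
    latching alarms that were never silenced keep sounding until a
    clinician silences them.
    """
    alarm.condition_active = False
    if not (alarm.latching and not alarm.acknowledged):
        state.active = [a for a in state.active if a is not alarm]


def apply_user_action(state: MonitorState, action: UserAction,
                      now: datetime,
                      pause_minutes: Optional[float] = 2.0) -> MonitorState:
    """Apply a clinician action (Silence / Pause / Resume) to the state.

    Silence acknowledges the currently announced alarms: audio stops,
    the message and flashing numeric persist while the condition does,
    and a latched alarm whose condition already ended is cleared.
    Pause suppresses audio for ``pause_minutes`` (``None`` = infinite,
    i.e. alarms disabled until Resume).
    """
    kind = action.action_kind
    if kind == "Silence":
        result = state.announce(now)
        for alarm in result.announced:
            alarm.acknowledged = True
        state.active = [a for a in state.active
                        if a.condition_active or not a.acknowledged]
    elif kind == "Pause Alarms":
        if pause_minutes is None:
            state.pause_infinite = True
            state.pause_until = None
        else:
            state.pause_infinite = False
            state.pause_until = now + timedelta(minutes=pause_minutes)
    elif kind == "Resume Alarms":
        state.pause_until = None
        state.pause_infinite = False
    else:
        raise ValueError(f"simulator cannot apply action kind {kind!r}")
    return state


def run_scenario(steps: Sequence[dict],
                 registry: Registry = DEFAULT_REGISTRY,
                 bed_label: str = "9001-S1",
                 device_name: str = "PIIC iX: ixsim001",
                 mrn: str = "0000000") -> tuple[list[AuditRecord],
                                                list["AnnouncementResult"]]:
    """Drive the simulator from a timed step list, emitting an audit log.

    Each step is a mapping with a ``t`` timestamp (ISO string or
    datetime) and one of ``raise`` (alarm message text), ``end``
    (message text of the alarm to end), or ``action`` (action message).
    The emitted rows are in the monitor's own dialect, so they feed
    straight back into the parser; sound rows are emitted whenever an
    audible alarm is newly announced.
    """
    state = MonitorState(registry=registry)
    records: list[AuditRecord] = []
    results: list[AnnouncementResult] = []
    announced_ids: set[int] = set()

    def emit(ts: datetime, message: str) -> None:
        records.append(AuditRecord(timestamp=ts, bed_label=bed_label,
                                   mrn=mrn, raw_message=message,
                                   device_name=device_name,
                                   row_index=len(records)))

    for step in steps:
        ts = step["t"]
        if isinstance(ts, str):
            ts = datetime.fromisoformat(ts)
        if "raise" in step:
            event = parse_message(step["raise"], registry)
            if not isinstance(event, (PhysiologicAlarm, TechnicalAlarm)):
                raise ValueError(f"not an alarm message: {step['raise']!r}")
            raise_alarm(state, event, ts)
            emit(ts, render_event(event))
        elif "end" in step:
            event = parse_message(step["end"], registry)
            target = next((a for a in state.active
                           if a.parameter == event.parameter
                           and a.condition_active), None)
            if target is None:
                raise ValueError(f"no active alarm to end: {step['end']!r}")
            end_condition(state, target, ts)
            ended = replace(target.event, status="ended")
            emit(ts, render_event(ended))
        elif "action" in step:
            event = parse_message(step["action"], registry)
            if not isinstance(event, UserAction):
                raise ValueError(f"not an action message: {step['action']!r}")
            apply_user_action(state, event, ts,
                              pause_minutes=step.get("pause_minutes", 2.0))
            emit(ts, render_event(event))
        else:
            raise ValueError(f"step needs 'raise', 'end' or 'action': {step}")

        result = state.announce(ts)
        results.append(result)
        for alarm in result.announced:
            if alarm.alarm_id not in announced_ids and alarm.audible_class:
                announced_ids.add(alarm.alarm_id)
                emit(ts, render_event(_sound_for(alarm)))
    return records, results


def _sound_for(alarm: ActiveAlarm) -> SoundEvent:
    pr = alarm.event.priority
    if pr.family == "technical":
        return SoundEvent(kind="inop")
    return SoundEvent(kind="red" if pr.level == 3 else "yellow")
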