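"""Message grammar for the "Alarm and Action" column.

A single free-text cell encodes up to six variables: the alarm priority
(number of ``*`` marks for physiologic alarms, ``!`` marks for technical
INOPs), the alarming parameter, the measured value that triggered it,
the programmed limit it crossed, the crossing direction, and whether the
alarm was generated or ended.  Clinician actions (silencing, pausing,
limit changes, admissions...) share the same column.  This module turns
each raw message into exactly one typed event.

Grammar sketch (whitespace flexible, status case-insensitive)::

    physiologic numerical   "**PAPd 18 >16 Generated."
    physiologic categorical "*Multiform PVCs Generated."
    apnea duration          "***Apnea 0:25 Generated."
    apnea overflow          "***Apnea > 20 sec Generated."
    technical (soft INOP)   "ECG Leads Off Generated."
    technical (hard INOP)   "!!!Batt Empty Generated."
    sound event             "Yellow alarm sound played."
    user action             "Silence." / "SpO2: Desat Limit 78."
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .records import clean_message
from .registry import DEFAULT_REGISTRY, Registry

__all__ = [
    "AlarmPriority", "PhysiologicAlarm", "TechnicalAlarm", "SoundEvent",
    "UserAction", "UnparsedEvent", "LimitChange", "ParsedEvent",
    "parse_message", "parse_limit_change", "render_event",
]


@dataclass(frozen=True)
class AlarmPriority:
    """Alarm priority as displayed by the monitor's mark count.

    Physiologic alarms run advisory (``*``, level 1) to high (``***``,
    level 3, shown red; level 2 is yellow).  Technical INOPs run soft
    (no mark, level 0, inaudible) through ``!!`` moderate to ``!!!``
    hard; single-``!`` INOPs occur in real exports and parse as level 1.
    """

    level: int
    family: str  # "physiologic" | "technical"

    def __post_init__(self) -> None:
        if self.family == "physiologic" and self.level not in (1, 2, 3):
            raise ValueError(f"physiologic level must be 1-3, got {self.level}")
        if self.family == "technical" and self.level not in (0, 1, 2, 3):
            raise ValueError(f"technical level must be 0-3, got {self.level}")
        if self.family not in ("physiologic", "technical"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def color(self) -> str:
        if self.family == "physiologic":
            return {3: "red", 2: "yellow", 1: "advisory"}[self.level]
        return "none"

    @property
    def marks(self) -> str:
        return ("*" if self.family == "physiologic" else "!") * self.level


@dataclass(frozen=True)
class LimitChange:
    """One reprogrammed alarm bound, sign preserved."""

    parameter: str
    lower: Optional[float] = None
    upper: Optional[float] = None


@dataclass(frozen=True)
class PhysiologicAlarm:
    priority: AlarmPriority
    parameter: str
    measurement_kind: str  # "numerical" | "categorical"
    status: str  # "generated" | "ended"
    trigger_value: Optional[float] = None
    limit_value: Optional[float] = None
    direction: str = "none"  # "above" | "below" | "none"
    apnea_detail: Optional[float] = None  # apnea duration, seconds
    apnea_over_20s: bool = False

    @property
    def is_numerical(self) -> bool:
        return self.measurement_kind == "numerical"


@dataclass(frozen=True)
class TechnicalAlarm:
    priority: AlarmPriority
    name: str
    status: str  # "generated" | "ended"

    @property
    def parameter(self) -> str:  # symmetry with PhysiologicAlarm
        return self.name

    measurement_kind: str = "categorical"  # all INOPs are categorical


@dataclass(frozen=True)
class SoundEvent:
    kind: str  # "red" | "yellow" | "inop"


@dataclass(frozen=True)
class UserAction:
    action_kind: str
    detail: str = ""
    limit_changes: tuple[LimitChange, ...] = ()


@dataclass(frozen=True)
class UnparsedEvent:
    """A message no grammar rule matched; carried, never dropped."""

    raw: str


ParsedEvent = Union[PhysiologicAlarm, TechnicalAlarm, SoundEvent,
                    UserAction, UnparsedEvent]

_NUM = r"-?\d+(?:\.\d+)?"

_SOUND_RE = re.compile(r"^(Red|Yellow) alarm sound played\.?$", re.IGNORECASE)
_INOP_SOUND_RE = re.compile(r"^INOP sound played\.?$", re.IGNORECASE)
_MARKS_RE = re.compile(r"^(\*{1,3}|!{1,3})\s*(.*)$")
_STATUS_RE = re.compile(r"^(.*?)\s*(Generated|Ended)\s*\.?$", re.IGNORECASE)
_NUMERICAL_RE = re.compile(
    rf"^(?P<param>.*\S)\s+(?P<value>{_NUM})\s*(?P<cmp>[<>])\s*(?P<limit>{_NUM})$")
_APNEA_CLOCK_RE = re.compile(r"^Apnea\s+(\d+):(\d{2})$", re.IGNORECASE)
_APNEA_OVER_RE = re.compile(r"^Apnea\s*>\s*(\d+)\s*sec$", re.IGNORECASE)

# Settings / limit-change forms
_SINGLE_LIMIT_RE = re.compile(
    rf"^(?:(?P<ctx>[\w\-/ ]+):\s*)?(?P<param>[\w\-/ ]+?)\s+Limit\s+"
    rf"(?P<value>{_NUM})\.?$")
_AL_LIMITS_RE = re.compile(r"^(?P<ctx>[\w\-/ ]+):\s*Al\.?\s*Limits\s+(?P<rest>.+?)\.?$")
_HIGH_LOW_RE = re.compile(
    rf"(?P<name>[\w\-/]+)\s+(?P<side>High|Low):\s*(?P<value>{_NUM})")
_TOGGLE_RE = re.compile(
    r"^(?:(?P<ctx>[\w\-/ ]+):\s*)?(?P<what>[\w\-/ ]+?)\s+(?P<state>On|Off)\.?$")

_ACTION_PATTERNS: tuple[tuple[re.Pattern, str], ...] = (
    (re.compile(r"^Silence\.?$", re.IGNORECASE), "Silence"),
    (re.compile(r"^Pause All Alarms\.?$", re.IGNORECASE), "Pause Alarms"),
    (re.compile(r"^Resume All Alarms\.?$", re.IGNORECASE), "Resume Alarms"),
    (re.compile(r"^Patient transferred to .+\.?$", re.IGNORECASE), "Transfer"),
    (re.compile(r"^Patient category set to .+\.?$", re.IGNORECASE),
     "Patient Category Changed"),
    (re.compile(r"^Pacer algorithm set to .+\.?$", re.IGNORECASE),
     "Paced Status Changed"),
    (re.compile(r"^Paced status .+\.?$", re.IGNORECASE), "Paced Status Changed"),
    (re.compile(r"^Equipment Offline\.?$", re.IGNORECASE), "Equipment Offline"),
    (re.compile(r"^Equipment Online\.?$", re.IGNORECASE), "Equipment Online"),
    (re.compile(r"^Stand ?By On\.?$", re.IGNORECASE), "Stand By On"),
    (re.compile(r"^Stand ?By Off\.?$", re.IGNORECASE), "Stand By Off"),
    (re.compile(r"^(Patient )?(admitted|Admission).*\.?$", re.IGNORECASE),
     "Admission"),
    (re.compile(r"^(Patient )?(discharged|Discharge).*\.?$", re.IGNORECASE),
     "Discharge"),
)


def _status(word: str) -> str:
    return word.lower()


def _priority_from_marks(marks: str) -> AlarmPriority:
    if marks.startswith("*"):
        return AlarmPriority(level=len(marks), family="physiologic")
    return AlarmPriority(level=len(marks), family="technical")


def _parse_physiologic(marks: str, body: str, status: str,
                       registry: Registry) -> ParsedEvent:
    priority = _priority_from_marks(marks)
    body = body.strip()

    m = _APNEA_CLOCK_RE.match(body)
    if m:
        seconds = 60 * int(m.group(1)) + int(m.group(2))
        return PhysiologicAlarm(priority, "Apnea", "numerical", status,
                                apnea_detail=float(seconds))
    m = _APNEA_OVER_RE.match(body)
    if m:
        return PhysiologicAlarm(priority, "Apnea", "numerical", status,
                                apnea_detail=float(m.group(1)),
                                apnea_over_20s=True)
    m = _NUMERICAL_RE.match(body)
    if m:
        param = registry.canonical(m.group("param"))
        direction = "above" if m.group("cmp") == ">" else "below"
        return PhysiologicAlarm(
            priority, param, "numerical", status,
            trigger_value=float(m.group("value")),
            limit_value=float(m.group("limit")),
            direction=direction)
    if not body:
        return UnparsedEvent(f"{marks} {status}")
    return PhysiologicAlarm(priority, registry.canonical(body),
                            "categorical", status)


def _parse_limit_forms(msg: str, registry: Registry) -> Optional[UserAction]:
    m = _AL_LIMITS_RE.match(msg)
    if m:
        bounds: dict[str, dict[str, float]] = {}
        for hm in _HIGH_LOW_RE.finditer(m.group("rest")):
            name = registry.canonical(hm.group("name"))
            side = "upper" if hm.group("side") == "High" else "lower"
            bounds.setdefault(name, {})[side] = float(hm.group("value"))
        if not bounds:
            return None
        changes = tuple(
            LimitChange(name, lower=b.get("lower"), upper=b.get("upper"))
            for name, b in bounds.items())
        return UserAction("Alarm Limit Change", detail=msg,
                          limit_changes=changes)
    m = _SINGLE_LIMIT_RE.match(msg)
    if m:
        param = registry.canonical(m.group("param"))
        value = float(m.group("value"))
        side = registry.lookup(param, numerical_hint=True).limit_side
        change = (LimitChange(param, upper=value) if side == "upper"
                  else LimitChange(param, lower=value))
        return UserAction("Alarm Limit Change", detail=msg,
                          limit_changes=(change,))
    return None


def _parse_action(msg: str, registry: Registry) -> Optional[UserAction]:
    for pattern, kind in _ACTION_PATTERNS:
        if pattern.match(msg):
            return UserAction(kind, detail=msg)
    limit = _parse_limit_forms(msg, registry)
    if limit is not None:
        return limit
    m = _TOGGLE_RE.match(msg)
    if m:
        state = m.group("state").capitalize()
        # "Arrhy: Missed Beat Off." toggles one alarm; a bare
        # "Arrhythmia Off." disables a whole measurement.
        kind = (f"Alarm {state}" if m.group("ctx")
                else f"Measurement {state}")
        return UserAction(kind, detail=msg)
    return None


def parse_message(raw: str, registry: Registry = DEFAULT_REGISTRY
                  ) -> ParsedEvent:
    """Parse one "Alarm and Action" message into a typed event.

    Every message maps to exactly one variant; text no rule matches
    comes back as :class:`UnparsedEvent` rather than being dropped.
    """
    msg = clean_message(raw)
    if not msg:
        raise ValueError("empty message")

    m = _SOUND_RE.match(msg)
    if m:
        return SoundEvent(kind=m.group(1).lower())
    if _INOP_SOUND_RE.match(msg):
        return SoundEvent(kind="inop")

    marks_m = _MARKS_RE.match(msg)
    marks, body = (marks_m.group(1), marks_m.group(2)) if marks_m else ("", msg)

    status_m = _STATUS_RE.match(body)
    if status_m:
        condition, status = status_m.group(1).strip(), _status(status_m.group(2))
        if marks.startswith("*"):
            return _parse_physiologic(marks, condition, status, registry)
        if condition:
            # soft INOPs carry no mark at all (and make no sound)
            priority = (_priority_from_marks(marks) if marks
                        else AlarmPriority(level=0, family="technical"))
            return TechnicalAlarm(priority, registry.canonical(condition),
                                  status)
        return UnparsedEvent(msg)

    if not marks:
        action = _parse_action(msg, registry)
        if action is not None:
            return action
    return UnparsedEvent(msg)


def parse_limit_change(raw: str, registry: Registry = DEFAULT_REGISTRY
                       ) -> Union[UserAction, UnparsedEvent]:
    """Parse a settings-form message into an Alarm Limit Change action.

    Accepts the single-bound form (``"SpO2: Desat Limit 78."``), the
    High/Low pair form (``"ST: Al. Limits ST-V2 High: 1.6 ST-V2 Low:
    -1.6."``, Unicode minus accepted), and alarm toggles (``"Arrhy:
    Missed Beat Off."`` parses as Alarm Off with no bounds).  A settings
    form without a numeric bound or toggle is returned unparsed.
    """
    msg = clean_message(raw)
    limit = _parse_limit_forms(msg, registry)
    if limit is not None:
        return limit
    m = _TOGGLE_RE.match(msg)
    if m and m.group("ctx"):
        return UserAction(f"Alarm {m.group('state').capitalize()}", detail=msg)
    return UnparsedEvent(msg)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def render_event(event: ParsedEvent) -> str:
    """Render a parsed alarm back to audit-log message text.

    For physiologic alarms the mark count round-trips exactly:
    ``parse_message(render_event(e))`` reproduces ``e``'s priority.
    """
    if isinstance(event, PhysiologicAlarm):
        status = event.status.capitalize()
        if event.apnea_over_20s:
            body = f"Apnea > {_fmt_num(event.apnea_detail)} sec"
        elif event.apnea_detail is not None:
            mm, ss = divmod(int(event.apnea_detail), 60)
            body = f"Apnea {mm}:{ss:02d}"
        elif event.is_numerical:
            cmp_ = ">" if event.direction == "above" else "<"
            body = (f"{event.parameter} {_fmt_num(event.trigger_value)} "
                    f"{cmp_}{_fmt_num(event.limit_value)}")
        else:
            body = event.parameter
        return f"{event.priority.marks}{body} {status}."
    if isinstance(event, TechnicalAlarm):
        return f"{event.priority.marks}{event.name} {event.status.capitalize()}."
    if isinstance(event, SoundEvent):
        if event.kind == "inop":
            return "INOP sound played."
        return f"{event.kind.capitalize()} alarm sound played."
    if isinstance(event, UserAction):
        return event.detail or f"{event.action_kind}."
    if isinstance(event, UnparsedEvent):
        return event.raw
    raise TypeError(f"cannot render {type(event).__name__}")
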