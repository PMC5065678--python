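"""Safety audits over parsed audit-log events.

Four checks, all deterministic and reproducible from the same input:

* **Limit scan** — harvest every programmed limit visible in the log
  (from numerical alarm messages and from Alarm Limit Change actions),
  report per-parameter observed min/max, and flag settings outside a
  site-supplied safe range.  The tool ships no clinical ranges of its
  own: what counts as safe is policy, supplied as configuration.
* **Priority consistency** — the same condition signature (parameter,
  crossing direction, programmed limit) alarming at different priority
  levels on different monitors indicates inconsistent configuration.
* **Unit compliance** — after a unit-wide settings change, any bed still
  raising an alarm of a supposedly disabled type has missed the change;
  the log names the bed.
* **Retrieval planning** — the central station retains 90 days of log
  and serves at most 50 days (at least 15 minutes) per retrieval, so a
  study period must be split into windows; spans beyond 90 days cannot
  be recovered retrospectively and need scheduled prospective pulls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .grammar import PhysiologicAlarm, TechnicalAlarm, UserAction
from .parsing import ParsedRecord
from .registry import DEFAULT_REGISTRY, Registry

__all__ = ["SafeRange", "SafeRangeSpec", "Finding", "LimitScanResult",
           "scan_limit_settings", "check_priority_consistency",
           "UnitExpectation", "check_unit_compliance",
           "RetrievalPlan", "plan_retrievals",
           "RETENTION_DAYS", "MAX_WINDOW_DAYS", "MIN_WINDOW_DAYS"]

RETENTION_DAYS = 90.0
MAX_WINDOW_DAYS = 50.0
MIN_WINDOW_DAYS = 15.0 / (24 * 60)  # 15 minutes


@dataclass(frozen=True)
class SafeRange:
    """Allowed interval for one parameter's programmed limit."""

    parameter: str
    side: str  # "lower" | "upper"
    low: float
    high: float
    severity: str = "unsafe"

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"interval bounds out of order for {self.parameter}")
        if self.side not in ("lower", "upper"):
            raise ValueError(f"side must be 'lower' or 'upper', got {self.side!r}")

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass
class SafeRangeSpec:
    """Site policy: one safe interval per (parameter, side).

    Ships empty by default — safe ranges are clinical policy, not a
    property of the log format.
    """

    ranges: dict[tuple[str, str], SafeRange] = field(default_factory=dict)

    def add(self, rng: SafeRange) -> None:
        key = (rng.parameter, rng.side)
        if key in self.ranges:
            raise ValueError(f"duplicate safe range for {key}")
        self.ranges[key] = rng

    @classmethod
    def from_file(cls, path: str | Path) -> "SafeRangeSpec":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text)) or {}
        spec = cls()
        entries = data if isinstance(data, list) else data.get("ranges", [])
        for entry in entries:
            spec.add(SafeRange(**entry))
        return spec


@dataclass(frozen=True)
class Finding:
    """One safety-audit result, traceable to its source rows."""

    kind: str  # "unsafe_limit" | "priority_inconsistency" | "noncompliant_bed"
    parameter: str
    bed_label: Optional[str]
    observed: tuple
    reference: tuple
    source_rows: tuple[int, ...]
    detail: str = ""
    trigger_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.source_rows:
            raise ValueError("a finding must cite at least one source row")


def _harvested_limits(parsed: Sequence[ParsedRecord]
                      ) -> list[tuple[str, str, float, str, int]]:
    """Yield (parameter, side, limit, bed, row) for every limit visible
    in the log.  A '>' crossing reveals the upper limit, '<' the lower;
    limit-change actions state the bound directly."""
    out = []
    for p in parsed:
        ev = p.event
        if isinstance(ev, PhysiologicAlarm) and ev.limit_value is not None:
            side = "upper" if ev.direction == "above" else "lower"
            out.append((ev.parameter, side, ev.limit_value,
                        p.record.bed_label, p.row_index))
        elif isinstance(ev, UserAction):
            for change in ev.limit_changes:
                if change.lower is not None:
                    out.append((change.parameter, "lower", change.lower,
                                p.record.bed_label, p.row_index))
                if change.upper is not None:
                    out.append((change.parameter, "upper", change.upper,
                                p.record.bed_label, p.row_index))
    return out


@dataclass
class LimitScanResult:
    findings: list[Finding]
    observed: dict[tuple[str, str], tuple[float, float]]  # (param, side) -> (min, max)
    unchecked: list[str]  # parameters seen but absent from the spec


def scan_limit_settings(parsed: Sequence[ParsedRecord],
                        spec: Optional[SafeRangeSpec] = None
                        ) -> LimitScanResult:
    """Report observed limit extremes and flag settings outside policy.

    One finding is emitted per distinct (bed, parameter, limit) outside
    the spec's interval; parameters without a spec entry are listed as
    unchecked rather than erroring.
    """
    spec = spec or SafeRangeSpec()
    harvested = _harvested_limits(parsed)

    observed: dict[tuple[str, str], tuple[float, float]] = {}
    for param, side, limit, _bed, _row in harvested:
        key = (param, side)
        lo, hi = observed.get(key, (limit, limit))
        observed[key] = (min(lo, limit), max(hi, limit))

    findings: list[Finding] = []
    unchecked: set[str] = set()
    by_setting: dict[tuple[str, str, str, float], list[int]] = {}
    for param, side, limit, bed, row in harvested:
        by_setting.setdefault((bed, param, side, limit), []).append(row)
    for (bed, param, side, limit), rows in sorted(by_setting.items()):
        rng = spec.ranges.get((param, side))
        if rng is None:
            unchecked.add(param)
            continue
        if not rng.contains(limit):
            findings.append(Finding(
                kind="unsafe_limit", parameter=param, bed_label=bed,
                observed=(limit,), reference=(rng.low, rng.high),
                source_rows=tuple(sorted(rows)),
                detail=(f"{param} {side} limit {limit:g} outside "
                        f"[{rng.low:g}, {rng.high:g}] on bed {bed}")))
    return LimitScanResult(findings=findings, observed=observed,
                           unchecked=sorted(unchecked))


def check_priority_consistency(parsed: Sequence[ParsedRecord]
                               ) -> list[Finding]:
    """Flag condition signatures alarming at more than one priority.

    Physiologic signature: (parameter, direction, limit) — the same
    threshold crossing should always carry the same number of marks.
    Technical signature: the INOP name alone.
    """
    groups: dict[tuple, dict] = {}
    for p in parsed:
        ev = p.event
        if isinstance(ev, PhysiologicAlarm):
            if ev.limit_value is None:
                continue  # categorical alarms carry no signature threshold
            sig = ("physiologic", ev.parameter, ev.direction, ev.limit_value)
            value = ev.trigger_value
        elif isinstance(ev, TechnicalAlarm):
            sig = ("technical", ev.name)
            value = None
        else:
            continue
        g = groups.setdefault(sig, {"levels": set(), "rows": [], "values": set()})
        g["levels"].add(ev.priority.level)
        g["rows"].append(p.row_index)
        if value is not None:
            g["values"].add(value)

    findings = []
    for sig in sorted(groups, key=str):
        g = groups[sig]
        if len(g["levels"]) < 2:
            continue
        parameter = sig[1]
        findings.append(Finding(
            kind="priority_inconsistency", parameter=parameter,
            bed_label=None, observed=tuple(sorted(g["levels"])),
            reference=(), source_rows=tuple(sorted(g["rows"])),
            trigger_values=tuple(sorted(g["values"])),
            detail=(f"{parameter} announced at priority levels "
                    f"{sorted(g['levels'])} for the same condition"
                    + (" (trigger values "
                       + ", ".join(f"{v:g}" for v in sorted(g["values"]))
                       + ")" if g["values"] else ""))))
    return findings


@dataclass
class UnitExpectation:
    """Intended unit-wide configuration to audit compliance against."""

    disabled_parameters: tuple[str, ...] = ()
    effective_date: Optional[datetime] = None
    require_disable_action: bool = False  # secondary evidence mode

    @classmethod
    def from_file(cls, path: str | Path) -> "UnitExpectation":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text)) or {}
        eff = data.get("effective_date")
        return cls(
            disabled_parameters=tuple(data.get("disabled_parameters", ())),
            effective_date=datetime.fromisoformat(eff) if eff else None,
            require_disable_action=bool(data.get("require_disable_action",
                                                 False)))


def check_unit_compliance(parsed: Sequence[ParsedRecord],
                          expectation: UnitExpectation,
                          registry: Registry = DEFAULT_REGISTRY
                          ) -> tuple[list[str], list[Finding]]:
    """Return (noncompliant beds, findings) for a unit settings change.

    Primary evidence: an alarm of a supposedly disabled type occurring
    after the effective date.  Secondary (opt-in): a bed that never
    logged an Alarm Off action for a disabled parameter.
    """
    disabled = {registry.canonical(p) for p in expectation.disabled_parameters}
    for param in disabled:
        if not registry.known(param):
            raise ValueError(f"expectation names unknown parameter {param!r}; "
                             f"register it first")

    findings: list[Finding] = []
    beds_seen: set[str] = set()
    disable_actions: dict[str, set[str]] = {}  # bed -> params toggled off
    offending: dict[tuple[str, str], list[int]] = {}
    for p in parsed:
        beds_seen.add(p.record.bed_label)
        ev = p.event
        after = (expectation.effective_date is None
                 or p.timestamp >= expectation.effective_date)
        if isinstance(ev, (PhysiologicAlarm, TechnicalAlarm)):
            param = registry.canonical(ev.parameter)
            if param in disabled and after:
                offending.setdefault((p.record.bed_label, param),
                                     []).append(p.row_index)
        elif isinstance(ev, UserAction) and ev.action_kind == "Alarm Off":
            for param in disabled:
                if param.lower() in ev.detail.lower():
                    disable_actions.setdefault(p.record.bed_label,
                                               set()).add(param)

    for (bed, param), rows in sorted(offending.items()):
        findings.append(Finding(
            kind="noncompliant_bed", parameter=param, bed_label=bed,
            observed=(len(rows),), reference=("disabled",),
            source_rows=tuple(sorted(rows)),
            detail=(f"bed {bed} raised {len(rows)} {param} alarm(s) although "
                    f"{param} should be disabled")))

    noncompliant = {bed for bed, _ in offending}
    if expectation.require_disable_action:
        for bed in beds_seen:
            missing = disabled - disable_actions.get(bed, set())
            if missing:
                noncompliant.add(bed)
    return sorted(noncompliant), findings


@dataclass(frozen=True)
class RetrievalPlan:
    """Windowed download schedule under the retention/window limits."""

    span_days: float
    windows: tuple[float, ...]  # window lengths, days
    retention_feasible: bool  # False: older data is already overwritten

    def describe(self) -> str:
        w = " + ".join(f"{x:g}" for x in self.windows)
        note = ("" if self.retention_feasible else
                " (exceeds the 90-day retention: retrospective data beyond "
                "90 days is overwritten; schedule prospective pulls)")
        return f"{len(self.windows)} window(s): {w} days{note}"


def plan_retrievals(span_days: float) -> RetrievalPlan:
    """Split a study span into retrieval windows of at most 50 days.

    Greedy full windows then the remainder: 90 days needs 2 retrievals
    (50 + 40), a 20-week project (140 days) needs 3 (50 + 50 + 40,
    flagged retention-infeasible for a purely retrospective pull).
    """
    if span_days < MIN_WINDOW_DAYS:
        raise ValueError(
            f"span {span_days:g} days is below the 15-minute minimum "
            f"retrieval period ({MIN_WINDOW_DAYS:g} days)")
    n_full, remainder = divmod(span_days, MAX_WINDOW_DAYS)
    windows = [MAX_WINDOW_DAYS] * int(n_full)
    if remainder > 1e-12:
        if remainder < MIN_WINDOW_DAYS and windows:
            # keep every window within [15 min, 50 days]
            borrow = MIN_WINDOW_DAYS - remainder
            windows[-1] -= borrow
            remainder = MIN_WINDOW_DAYS
        windows.append(remainder)
    assert len(windows) == math.ceil(span_days / MAX_WINDOW_DAYS)
    return RetrievalPlan(span_days=span_days, windows=tuple(windows),
                         retention_feasible=span_days <= RETENTION_DAYS)
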