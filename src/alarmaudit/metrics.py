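"""Alarm-rate reports, action summaries, and pre/post comparisons.

Alarm burden is comparable across units and studies only when the
denominator is explicit, so every report carries one: bed-days (distinct
bed x calendar-day pairs observed in the log — an approximation of
census-based patient-days that is exact when every monitored bed is
occupied all day), patient-days, or the elapsed hours or minutes of the
log.  Counts can be grouped by parameter, priority, bed, measurement
kind, and audibility; soft INOPs make no sound, so the audible filter
drops them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

import pandas as pd

from .grammar import PhysiologicAlarm, TechnicalAlarm, UserAction
from .parsing import ParsedRecord

__all__ = ["RateReport", "PeriodComparison", "compute_rates",
           "summarize_actions", "compare_periods"]

GROUPABLE = ("parameter", "priority", "bed", "measurement_kind", "audible")
DENOMINATORS = ("bed-days", "patient-days", "hours", "minutes")


@dataclass
class RateReport:
    """Counts and rates per group, with an explicit denominator."""

    grouping: tuple[str, ...]
    table: pd.DataFrame  # group columns + "count" + "rate"
    denominator: str
    denominator_value: float
    total: int

    def to_text(self) -> str:
        lines = [f"denominator: {self.denominator_value:g} {self.denominator}",
                 f"total alarm events: {self.total}"]
        unit = self.denominator.rstrip("s")
        for _, row in self.table.iterrows():
            group = ", ".join(f"{g}={row[g]}" for g in self.grouping) or "all"
            lines.append(f"  {group}: count={int(row['count'])} "
                         f"rate={row['rate']:.4g} per {unit}")
        return "\n".join(lines)


@dataclass
class PeriodComparison:
    pre: Optional[RateReport]
    post: Optional[RateReport]
    deltas: pd.DataFrame  # group cols + rate_pre, rate_post, abs/pct change
    pre_empty: bool = False
    post_empty: bool = False


def _is_alarm(p: ParsedRecord) -> bool:
    return isinstance(p.event, (PhysiologicAlarm, TechnicalAlarm))


def _is_audible(p: ParsedRecord) -> bool:
    ev = p.event
    # soft INOPs (no priority mark) are the one inaudible alarm class
    return not (isinstance(ev, TechnicalAlarm) and ev.priority.level == 0)


def _priority_label(p: ParsedRecord) -> str:
    ev = p.event
    if isinstance(ev, PhysiologicAlarm):
        return ev.priority.color  # red / yellow / advisory
    return "INOP"


def _alarm_frame(parsed: Sequence[ParsedRecord], status: str) -> pd.DataFrame:
    rows = []
    for p in parsed:
        if not _is_alarm(p):
            continue
        if status != "all" and p.event.status != status:
            continue
        rows.append({
            "parameter": p.event.parameter,
            "priority": _priority_label(p),
            "bed": p.record.bed_label,
            "measurement_kind": p.event.measurement_kind,
            "audible": _is_audible(p),
            "timestamp": p.timestamp,
        })
    return pd.DataFrame(rows, columns=["parameter", "priority", "bed",
                                       "measurement_kind", "audible",
                                       "timestamp"])


def _denominator_value(parsed: Sequence[ParsedRecord], denominator: str,
                       census: Optional[float]) -> float:
    if census is not None:
        return float(census)
    if not parsed:
        raise ValueError("cannot derive a denominator from an empty log")
    if denominator in ("bed-days", "patient-days"):
        pairs = set()
        for p in parsed:
            who = (p.record.bed_label if denominator == "bed-days"
                   else p.record.patient_key)
            pairs.add((who, p.timestamp.date()))
        return float(len(pairs))
    ts = [p.timestamp for p in parsed]
    span_s = (max(ts) - min(ts)).total_seconds()
    if span_s <= 0:
        raise ValueError("log spans zero time; supply a census denominator")
    return span_s / 3600.0 if denominator == "hours" else span_s / 60.0


def compute_rates(parsed: Sequence[ParsedRecord],
                  grouping: Sequence[str] = ("parameter",),
                  denominator: str = "bed-days",
                  *, census: Optional[float] = None,
                  audible_only: bool = False,
                  status: str = "generated") -> RateReport:
    """Count alarm events per group and normalize by the denominator.

    ``status`` selects which log rows count as one alarm event:
    ``"generated"`` (default — one count per alarm occurrence) or
    ``"all"`` (every alarm row, generations and ends alike).
    Group marginal totals are additive: refining the grouping never
    changes the grand total.
    """
    grouping = tuple(grouping)
    for g in grouping:
        if g not in GROUPABLE:
            raise ValueError(f"cannot group by {g!r}; choose from {GROUPABLE}")
    if denominator not in DENOMINATORS:
        raise ValueError(f"unknown denominator {denominator!r}")

    denom = _denominator_value(parsed, denominator, census)
    if denom <= 0:
        raise ValueError("denominator must be positive")

    frame = _alarm_frame(parsed, status)
    if audible_only and not frame.empty:
        frame = frame[frame["audible"]]
    total = len(frame)
    if grouping:
        counts = (frame.groupby(list(grouping), observed=True)
                  .size().reset_index(name="count")
                  .sort_values(list(grouping), kind="stable")
                  .reset_index(drop=True))
    else:
        counts = pd.DataFrame({"count": [total]})
    counts["rate"] = counts["count"] / denom
    return RateReport(grouping=grouping, table=counts,
                      denominator=denominator, denominator_value=denom,
                      total=total)


def summarize_actions(parsed: Sequence[ParsedRecord]) -> Counter:
    """Count clinician actions per taxonomy kind; each action once."""
    return Counter(p.event.action_kind for p in parsed
                   if isinstance(p.event, UserAction))


def compare_periods(parsed: Sequence[ParsedRecord], boundary_ts: datetime,
                    grouping: Sequence[str] = ("parameter",),
                    denominator: str = "bed-days",
                    *, status: str = "generated") -> PeriodComparison:
    """Split the log at ``boundary_ts`` and compare per-group rates.

    Events strictly before the boundary are "pre"; the rest are "post".
    An empty side is flagged and its rates reported as absent (NaN),
    never as zero.
    """
    ts = [p.timestamp for p in parsed]
    if ts and not (min(ts) <= boundary_ts <= max(ts)):
        raise ValueError("boundary timestamp lies outside the data range")
    pre_events = [p for p in parsed if p.timestamp < boundary_ts]
    post_events = [p for p in parsed if p.timestamp >= boundary_ts]

    def _side(events: list[ParsedRecord]) -> Optional[RateReport]:
        if not events:
            return None
        return compute_rates(events, grouping, denominator, status=status)

    pre, post = _side(pre_events), _side(post_events)
    group_cols = list(grouping)

    def _rates(report: Optional[RateReport], name: str) -> pd.DataFrame:
        if report is None:
            return pd.DataFrame(columns=group_cols + [name])
        t = report.table[group_cols + ["rate"]].copy()
        return t.rename(columns={"rate": name})

    deltas = _rates(pre, "rate_pre").merge(
        _rates(post, "rate_post"), on=group_cols, how="outer")
    # a group absent on one side genuinely had zero events there —
    # distinct from a whole side being empty, which stays NaN
    if pre is not None:
        deltas["rate_pre"] = deltas["rate_pre"].fillna(0.0)
    if post is not None:
        deltas["rate_post"] = deltas["rate_post"].fillna(0.0)
    deltas["abs_change"] = deltas["rate_post"] - deltas["rate_pre"]
    deltas["pct_change"] = 100.0 * deltas["abs_change"] / deltas["rate_pre"]
    deltas = deltas.sort_values(group_cols, kind="stable").reset_index(drop=True)
    return PeriodComparison(pre=pre, post=post, deltas=deltas,
                            pre_empty=pre is None, post_empty=post is None)
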