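"""Synthetic audit-log generator with known ground truth.

Real audit logs cannot leave the hospital, so every analysis path in
this package is exercised against generated logs whose true episode
list, rates, and planted anomalies are known by construction.  The
generator emulates the record mix of a busy cardiac-ICU unit log:
numerical yellow/red alarms with values and limits, categorical
arrhythmia and INOP alarms, alarm-sound rows, clinician actions, paired
Generated/Ended rows — including the logger's quirk of writing the end
row *before* the generation row for alarms shorter than one second —
and optional connectivity gaps that silently swallow an interval of
records.

Alarm onsets are Poisson per parameter x bed; episode durations are
exponential, rounded to the log's 1-second resolution.  The same seed
always yields a byte-identical log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .records import AuditRecord

__all__ = ["AlarmMixEntry", "PlantedLimit", "PlantedPriorityPair",
           "PlantedDisabledAlarm", "SynthConfig", "TrueEpisode",
           "GroundTruth", "generate_log", "records_to_vendor_tsv"]


@dataclass(frozen=True)
class AlarmMixEntry:
    """One alarm stream: a parameter alarming at a fixed priority.

    ``rate_per_bed_day`` is the expected number of episodes per bed per
    day; ``mean_duration_s`` the exponential mean episode length.  For
    numerical alarms ``limit``/``direction`` define the programmed
    threshold; trigger values are drawn just past it.
    """

    parameter: str
    marks: str  # "*".."***" physiologic, ""/"!"/"!!"/"!!!" technical
    rate_per_bed_day: float
    mean_duration_s: float = 30.0
    limit: Optional[float] = None
    direction: Optional[str] = None  # "above" | "below"
    technical: bool = False

    def __post_init__(self) -> None:
        if self.rate_per_bed_day < 0:
            raise ValueError(f"negative rate for {self.parameter}")
        if (self.limit is None) != (self.direction is None):
            raise ValueError(f"{self.parameter}: limit and direction "
                             f"must be given together")


# Default record mix: the common numerical yellow alarms, a red
# desaturation stream, an advisory arrhythmia, and soft/moderate INOPs,
# at rates typical of a monitored cardiac ICU bed (tens of alarms per
# bed-day, dominated by yellow limit alarms).
DEFAULT_ALARM_MIX: tuple[AlarmMixEntry, ...] = (
    AlarmMixEntry("HR", "**", 12.0, 25.0, limit=120, direction="above"),
    AlarmMixEntry("Desat", "***", 8.0, 40.0, limit=88, direction="below"),
    AlarmMixEntry("RR", "**", 6.0, 30.0, limit=30, direction="above"),
    AlarmMixEntry("ABPs", "**", 6.0, 35.0, limit=160, direction="above"),
    AlarmMixEntry("PAPd", "**", 4.0, 20.0, limit=16, direction="above"),
    AlarmMixEntry("SpO2", "**", 5.0, 45.0, limit=90, direction="below"),
    AlarmMixEntry("Multiform PVCs", "*", 3.0, 15.0),
    AlarmMixEntry("ECG Leads Off", "", 5.0, 60.0, technical=True),
    AlarmMixEntry("Check Equipment", "!!", 1.0, 120.0, technical=True),
)

DEFAULT_ACTION_RATES: dict[str, float] = {
    "Silence.": 10.0,
    "Pause All Alarms.": 2.0,
    "Resume All Alarms.": 2.0,
    "SpO2: Desat Limit 85.": 0.5,
    "Patient category set to Adult.": 0.3,
}


@dataclass(frozen=True)
class PlantedLimit:
    """An alarm emitted with a deliberately chosen programmed limit."""

    bed_index: int
    parameter: str = "Desat"
    marks: str = "***"
    direction: str = "below"
    limit: float = 50.0
    value: float = 44.0


@dataclass(frozen=True)
class PlantedPriorityPair:
    """The same condition signature emitted at two priority levels."""

    parameter: str = "HR"
    direction: str = "above"
    limit: float = 150.0
    value: float = 153.0
    levels: tuple[int, int] = (1, 2)
    bed_indices: tuple[int, int] = (0, 1)


@dataclass(frozen=True)
class PlantedDisabledAlarm:
    """A categorical alarm on a bed where it was meant to be disabled."""

    bed_index: int
    parameter: str = "Pair PVCs"
    marks: str = "*"


@dataclass
class SynthConfig:
    """Study conditions for one generated unit log.

    Defaults model the reference setting: a 20-bed transplant cardiac
    ICU logging for one day, with masked MRNs.  ``rate_change_factor``
    scales all alarm rates after ``change_boundary_fraction`` of the
    span, for pre/post-intervention experiments.  ``gaps`` are
    connectivity losses given as (start, end) fractions of the span;
    records inside them are deleted and noted in the manifest.
    """

    n_beds: int = 20
    duration_days: float = 1.0
    start: datetime = field(default_factory=lambda: datetime(2014, 4, 20))
    alarms: tuple[AlarmMixEntry, ...] = DEFAULT_ALARM_MIX
    action_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTION_RATES))
    seed: int = 0
    emit_sound_rows: bool = True
    rate_change_factor: float = 1.0
    change_boundary_fraction: float = 0.5
    planted_limits: tuple[PlantedLimit, ...] = ()
    planted_priority_pairs: tuple[PlantedPriorityPair, ...] = ()
    planted_disabled: tuple[PlantedDisabledAlarm, ...] = ()
    gaps: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_beds <= 0 or self.duration_days <= 0:
            raise ValueError("n_beds and duration_days must be positive")
        for entry in self.alarms:
            if entry.rate_per_bed_day < 0:
                raise ValueError("alarm rates must be non-negative")
        for rate in self.action_rates.values():
            if rate < 0:
                raise ValueError("action rates must be non-negative")
        for lo, hi in self.gaps:
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("gaps must be (lo, hi) fractions in [0, 1]")

    def bed_label(self, i: int) -> str:
        return f"{9001 + 2 * i}-S1"

    def device_name(self, i: int) -> str:
        return f"PIIC iX: ixsurv{1 + i % 3:03d}"


@dataclass(frozen=True)
class TrueEpisode:
    bed_label: str
    device_name: str
    parameter: str
    marks: str
    start: datetime
    end: datetime
    duration_s: float
    in_gap: bool = False  # a gap swallowed at least one of its rows


@dataclass
class GroundTruth:
    episodes: list[TrueEpisode]
    configured_rates: dict[str, float]  # parameter -> episodes/bed-day (pre)
    action_counts: dict[str, int]  # emitted action rows per message
    manifest: dict  # planted anomalies and gaps

    def episode_count(self, parameter: Optional[str] = None) -> int:
        return sum(1 for e in self.episodes
                   if parameter is None or e.parameter == parameter)


def _round_ts(base: datetime, offset_s: float) -> datetime:
    return base + timedelta(seconds=int(round(offset_s)))


def _alarm_message(param: str, marks: str, value: Optional[float],
                   limit: Optional[float], direction: Optional[str],
                   status: str) -> str:
    if limit is None:
        return f"{marks}{param} {status}."
    cmp_ = ">" if direction == "above" else "<"
    v = int(value) if float(value).is_integer() else value
    l = int(limit) if float(limit).is_integer() else limit
    return f"{marks}{param} {v} {cmp_}{l} {status}."


def _sound_message(marks: str, technical: bool) -> Optional[str]:
    if technical:
        return None if marks == "" else "INOP sound played."
    return ("Red alarm sound played." if marks == "***"
            else "Yellow alarm sound played." if marks == "**" else None)


def generate_log(config: SynthConfig) -> tuple[list[AuditRecord], GroundTruth]:
    """Generate one unit audit log and its ground truth.

    Returns records in file order (chronological; same-second ties in
    emission order, with sub-second episodes writing Ended before
    Generated) and a :class:`GroundTruth` consistent with them by
    construction.
    """
    rng = np.random.default_rng(config.seed)
    span_s = config.duration_days * 86400.0
    window_end = config.start + timedelta(seconds=span_s)
    boundary_s = span_s * config.change_boundary_fraction

    # (ts, tie, message, bed_index); tie orders same-second rows
    rows: list[tuple[datetime, int, str, int]] = []
    tie = 0
    truth_eps: list[TrueEpisode] = []

    def next_tie() -> int:
        nonlocal tie
        tie += 1
        return tie

    def emit_episode(bed_i: int, entry: AlarmMixEntry, onset_s: float,
                     duration_s: float, *, value: Optional[float] = None,
                     end_value: Optional[float] = None) -> None:
        start_ts = _round_ts(config.start, onset_s)
        end_ts = min(_round_ts(config.start, onset_s + duration_s),
                     window_end)
        if end_ts < start_ts:
            end_ts = start_ts
        dur = (end_ts - start_ts).total_seconds()
        _emit_rows(bed_i, entry, start_ts, end_ts, dur, value, end_value)

    def _emit_rows(bed_i, entry, start_ts, end_ts, dur, value, end_value):
        gen_msg = _alarm_message(entry.parameter, entry.marks, value,
                                 entry.limit, entry.direction, "Generated")
        end_msg = _alarm_message(entry.parameter, entry.marks, end_value,
                                 entry.limit, entry.direction, "Ended")
        if dur == 0.0:
            # shorter than a second: logger writes the end row first
            rows.append((start_ts, next_tie(), end_msg, bed_i))
            rows.append((start_ts, next_tie(), gen_msg, bed_i))
        else:
            rows.append((start_ts, next_tie(), gen_msg, bed_i))
            rows.append((end_ts, next_tie(), end_msg, bed_i))
        if config.emit_sound_rows:
            sound = _sound_message(entry.marks, entry.technical)
            if sound is not None:
                rows.append((start_ts, next_tie(), sound, bed_i))
        truth_eps.append(TrueEpisode(
            bed_label=config.bed_label(bed_i),
            device_name=config.device_name(bed_i),
            parameter=entry.parameter, marks=entry.marks,
            start=start_ts, end=end_ts, duration_s=dur))

    def draw_value(entry: AlarmMixEntry) -> float:
        span = max(1.0, abs(entry.limit) * 0.1)
        delta = float(np.floor(rng.uniform(0, span))) + 1.0
        return (entry.limit + delta if entry.direction == "above"
                else entry.limit - delta)

    def poisson_onsets(rate_per_day: float) -> np.ndarray:
        """Onset offsets honoring the pre/post rate-change factor."""
        pre_days = boundary_s / 86400.0
        post_days = config.duration_days - pre_days
        n_pre = rng.poisson(rate_per_day * pre_days)
        n_post = rng.poisson(rate_per_day * config.rate_change_factor
                             * post_days)
        pre = rng.uniform(0.0, boundary_s, size=n_pre)
        post = rng.uniform(boundary_s, span_s, size=n_post)
        return np.sort(np.concatenate([pre, post]))

    for bed_i in range(config.n_beds):
        for entry in config.alarms:
            # one alarm stream cannot re-trigger while already active:
            # thin onsets that would overlap the running episode
            prev_end_s = -2.0
            for onset in poisson_onsets(entry.rate_per_bed_day):
                duration = rng.exponential(entry.mean_duration_s)
                start_r = float(round(onset))
                if start_r <= prev_end_s + 1.0:
                    continue
                end_r = min(float(round(onset + duration)), span_s)
                prev_end_s = max(end_r, start_r)
                value = end_value = None
                if entry.limit is not None:
                    value, end_value = draw_value(entry), draw_value(entry)
                emit_episode(bed_i, entry, float(onset), duration,
                             value=value, end_value=end_value)
        for message, rate in sorted(config.action_rates.items()):
            for onset in poisson_onsets(rate):
                rows.append((_round_ts(config.start, float(onset)),
                             next_tie(), message, bed_i))

    # planted anomalies: one deterministic episode each
    for p in config.planted_limits:
        entry = AlarmMixEntry(p.parameter, p.marks, 0.0, limit=p.limit,
                              direction=p.direction)
        onset = float(rng.uniform(0.0, span_s * 0.9))
        emit_episode(p.bed_index % config.n_beds, entry, onset, 10.0,
                     value=p.value, end_value=p.value)
    for p in config.planted_priority_pairs:
        for level, bed_i in zip(p.levels, p.bed_indices):
            entry = AlarmMixEntry(p.parameter, "*" * level, 0.0,
                                  limit=p.limit, direction=p.direction)
            onset = float(rng.uniform(0.0, span_s * 0.9))
            emit_episode(bed_i % config.n_beds, entry, onset, 10.0,
                         value=p.value, end_value=p.value)
    for p in config.planted_disabled:
        entry = AlarmMixEntry(p.parameter, p.marks, 0.0)
        onset = float(rng.uniform(0.0, span_s * 0.9))
        emit_episode(p.bed_index % config.n_beds, entry, onset, 10.0)

    rows.sort(key=lambda r: (r[0], r[1]))

    # connectivity gaps delete every record in the interval
    gap_windows = [(config.start + timedelta(seconds=lo * span_s),
                    config.start + timedelta(seconds=hi * span_s))
                   for lo, hi in config.gaps]

    def in_gap(ts: datetime) -> bool:
        return any(lo <= ts < hi for lo, hi in gap_windows)

    deleted = sum(1 for ts, _, _, _ in rows if in_gap(ts))
    kept = [(ts, t, msg, bed) for ts, t, msg, bed in rows if not in_gap(ts)]

    if gap_windows:
        truth_eps = [
            e if not (in_gap(e.start) or in_gap(e.end))
            else TrueEpisode(e.bed_label, e.device_name, e.parameter,
                             e.marks, e.start, e.end, e.duration_s,
                             in_gap=True)
            for e in truth_eps]

    records = [AuditRecord(timestamp=ts, bed_label=config.bed_label(bed),
                           mrn="0000000", raw_message=msg,
                           device_name=config.device_name(bed), row_index=i)
               for i, (ts, _, msg, bed) in enumerate(kept)]

    action_counts: dict[str, int] = {}
    for ts, _, msg, _ in kept:
        if msg in config.action_rates:
            action_counts[msg] = action_counts.get(msg, 0) + 1

    truth = GroundTruth(
        episodes=sorted(truth_eps, key=lambda e: (e.start, e.bed_label,
                                                  e.parameter, e.marks)),
        configured_rates={e.parameter: e.rate_per_bed_day
                          for e in config.alarms},
        action_counts=action_counts,
        manifest={
            "seed": config.seed,
            "n_beds": config.n_beds,
            "duration_days": config.duration_days,
            "rate_change_factor": config.rate_change_factor,
            "planted_limits": [vars(p) for p in config.planted_limits],
            "planted_priority_pairs": [
                {**{k: v for k, v in vars(p).items()}}
                for p in config.planted_priority_pairs],
            "planted_disabled": [vars(p) for p in config.planted_disabled],
            "gaps": list(config.gaps),
            "records_deleted_by_gaps": deleted,
        })
    return records, truth


def records_to_vendor_tsv(records: Sequence[AuditRecord]) -> str:
    """Render records in the central station's own export dialect."""
    lines = ["Date\tBed label\tMRN\tAlarm and Action\tDevice name"]
    for r in records:
        ts = r.timestamp
        date = (f"{ts.month}/{ts.day}/{ts.year % 100:02d} "
                f"{ts.hour}:{ts.minute:02d}:{ts.second:02d}")
        lines.append(f"{date}\t{r.bed_label}\t{r.mrn}\t{r.raw_message}\t"
                     f"{r.device_name}")
    return "\n".join(lines) + "\n"
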