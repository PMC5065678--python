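"""Pair Generated/Ended alarm events into episodes with durations.

The central station logs the start and the end of one alarm as two
separate, unconnected rows.  Alarm duration — the key proxy for
clinician response time and a driver of alarm fatigue — therefore has
to be reconstructed: sort events by patient identity, bed, device and
parameter, then match each Ended to the nearest preceding unmatched
Generated with the same key.  One wrinkle: for alarms that signal for
less than a second the logger records the end row *before* the
generation row (at the same second), so a same-second Ended/Generated
inversion pairs as a zero-duration episode.

Events whose partner lies outside the retrieved window are censored:
a lone Generated is right-censored at the window end, a lone Ended is
left-censored at the window start.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from .grammar import PhysiologicAlarm, TechnicalAlarm
from .parsing import ParsedRecord

__all__ = ["EpisodeKey", "AlarmEpisode", "PairingResult", "pair_episodes",
           "episode_conservation_check", "episodes_to_frame"]


class EpisodeKey(NamedTuple):
    """Identity of one alarm stream.

    Patient identity falls back to bed+device when the MRN is masked.
    Priority is part of the key: the same parameter alarming at two
    different priorities is two distinct audible experiences and forms
    two episode streams.
    """

    patient: str
    bed_label: str
    device_name: str
    parameter: str
    priority_marks: str


@dataclass(frozen=True)
class AlarmEpisode:
    key: EpisodeKey
    start_ts: datetime
    end_ts: datetime
    duration_s: float
    start_value: Optional[float] = None
    end_value: Optional[float] = None
    left_censored: bool = False
    right_censored: bool = False
    gen_row: Optional[int] = None
    end_row: Optional[int] = None

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("episode duration must be non-negative")


@dataclass
class PairingResult:
    episodes: list[AlarmEpisode]
    unmatched: list[ParsedRecord]  # anomalies that formed no episode
    window: tuple[datetime, datetime]


def _is_alarm(p: ParsedRecord) -> bool:
    return isinstance(p.event, (PhysiologicAlarm, TechnicalAlarm))


def _key_of(p: ParsedRecord) -> EpisodeKey:
    ev = p.event
    return EpisodeKey(
        patient=p.record.patient_key,
        bed_label=p.record.bed_label,
        device_name=p.record.device_name,
        parameter=ev.parameter,
        priority_marks=ev.priority.marks,
    )


def _value_of(p: ParsedRecord) -> Optional[float]:
    ev = p.event
    if isinstance(ev, PhysiologicAlarm):
        return ev.trigger_value if ev.trigger_value is not None else ev.apnea_detail
    return None


def pair_episodes(parsed: Sequence[ParsedRecord],
                  window: Optional[tuple[datetime, datetime]] = None
                  ) -> PairingResult:
    """Pair alarm events into episodes.

    Matching is a pure function of the (key, timestamp, row_index)-sorted
    event sequence, so any permutation of the input rows yields the same
    episodes.  Non-alarm events (sounds, actions, unparsed rows) are
    ignored here.
    """
    alarms = [p for p in parsed if _is_alarm(p)]
    if window is None:
        if alarms:
            ts = [p.timestamp for p in alarms]
            window = (min(ts), max(ts))
        else:
            now = datetime(1970, 1, 1)
            window = (now, now)
    w_start, w_end = window

    by_key: dict[EpisodeKey, list[ParsedRecord]] = {}
    for p in sorted(alarms, key=lambda p: (p.timestamp, p.row_index)):
        by_key.setdefault(_key_of(p), []).append(p)

    episodes: list[AlarmEpisode] = []
    unmatched: list[ParsedRecord] = []

    for key in sorted(by_key):
        group = by_key[key]
        open_gens: list[ParsedRecord] = []
        consumed: set[int] = set()
        for i, p in enumerate(group):
            if p.row_index in consumed:
                continue
            status = p.event.status
            if status == "generated":
                open_gens.append(p)
                continue
            # status == "ended"
            if open_gens:
                gen = open_gens.pop()  # nearest preceding unmatched
                episodes.append(AlarmEpisode(
                    key, gen.timestamp, p.timestamp,
                    (p.timestamp - gen.timestamp).total_seconds(),
                    start_value=_value_of(gen), end_value=_value_of(p),
                    gen_row=gen.row_index, end_row=p.row_index))
                continue
            # sub-second inversion: the logger wrote the end row before
            # the generation row within the same second
            partner = next(
                (q for q in group[i + 1:]
                 if q.row_index not in consumed
                 and q.event.status == "generated"
                 and q.timestamp == p.timestamp),
                None)
            if partner is not None:
                consumed.add(partner.row_index)
                episodes.append(AlarmEpisode(
                    key, partner.timestamp, partner.timestamp, 0.0,
                    start_value=_value_of(partner), end_value=_value_of(p),
                    gen_row=partner.row_index, end_row=p.row_index))
                continue
            # Ended with no generation in the window: left-censored
            episodes.append(AlarmEpisode(
                key, w_start, p.timestamp,
                max((p.timestamp - w_start).total_seconds(), 0.0),
                end_value=_value_of(p), left_censored=True,
                end_row=p.row_index))
        for gen in open_gens:  # generations with no end: right-censored
            episodes.append(AlarmEpisode(
                key, gen.timestamp, w_end,
                max((w_end - gen.timestamp).total_seconds(), 0.0),
                start_value=_value_of(gen), right_censored=True,
                gen_row=gen.row_index))

    episodes.sort(key=lambda e: (e.start_ts, e.gen_row if e.gen_row is not None
                                 else e.end_row or 0))
    return PairingResult(episodes=episodes, unmatched=unmatched, window=window)


@dataclass
class ConservationReport:
    ok: bool
    n_events: int
    n_episodes: int
    problems: list[str]


def episode_conservation_check(parsed: Sequence[ParsedRecord],
                               result: PairingResult) -> ConservationReport:
    """Verify that pairing neither lost nor duplicated any alarm event.

    Every alarm row must land in exactly one episode or in the unmatched
    report, and episode counts must equal consumed generations plus
    left-censored ends.
    """
    problems: list[str] = []
    alarm_rows = {p.row_index for p in parsed if _is_alarm(p)}
    seen: list[int] = []
    for ep in result.episodes:
        for row in (ep.gen_row, ep.end_row):
            if row is not None:
                seen.append(row)
    seen += [p.row_index for p in result.unmatched]
    if len(seen) != len(set(seen)):
        dupes = sorted({r for r in seen if seen.count(r) > 1})
        problems.append(f"rows used more than once: {dupes}")
    missing = alarm_rows - set(seen)
    extra = set(seen) - alarm_rows
    if missing:
        problems.append(f"alarm rows unaccounted for: {sorted(missing)}")
    if extra:
        problems.append(f"non-alarm rows consumed: {sorted(extra)}")
    n_gen_consumed = sum(1 for ep in result.episodes if ep.gen_row is not None)
    n_left = sum(1 for ep in result.episodes if ep.left_censored)
    if n_gen_consumed + n_left != len(result.episodes):
        problems.append(
            f"episode count {len(result.episodes)} != consumed generations "
            f"{n_gen_consumed} + left-censored {n_left}")
    return ConservationReport(ok=not problems, n_events=len(alarm_rows),
                              n_episodes=len(result.episodes),
                              problems=problems)


def episodes_to_frame(episodes: Sequence[AlarmEpisode]) -> pd.DataFrame:
    """One row per episode, ready for CSV export or rate analysis."""
    return pd.DataFrame([{
        "patient": e.key.patient,
        "bed_label": e.key.bed_label,
        "device_name": e.key.device_name,
        "parameter": e.key.parameter,
        "priority": e.key.priority_marks,
        "start_ts": e.start_ts.isoformat(),
        "end_ts": e.end_ts.isoformat(),
        "duration_s": e.duration_s,
        "start_value": e.start_value,
        "end_value": e.end_value,
        "left_censored": e.left_censored,
        "right_censored": e.right_censored,
        "gen_row": e.gen_row,
        "end_row": e.end_row,
    } for e in episodes])
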