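"""Independent reference implementations used only by the tests.

These re-derive expected results by direct, unoptimized evaluation of
the stated rules, structured differently from the library code so that
agreement is evidence rather than tautology.
"""

from __future__ import annotations

from alarmaudit.grammar import PhysiologicAlarm, TechnicalAlarm
from alarmaudit.parsing import ParsedRecord


def _key(p: ParsedRecord) -> tuple:
    return (p.record.patient_key, p.record.bed_label, p.record.device_name,
            p.event.parameter, p.event.priority.marks)


def brute_force_episodes(parsed: list[ParsedRecord],
                         window=None) -> set[tuple]:
    """Exhaustive backward/forward-scan episode matcher.

    For every Ended event, in chronological order, scan backwards over
    the whole event list for the latest unconsumed Generated of the same
    key; failing that, scan forward for a same-second Generated (the
    sub-second inversion); failing that, the end is left-censored.
    Generations never consumed are right-censored at the window end.
    Returns the episode multiset as frozen tuples.
    """
    alarms = [p for p in parsed
              if isinstance(p.event, (PhysiologicAlarm, TechnicalAlarm))]
    if window is None:
        ts = [p.timestamp for p in alarms]
        window = (min(ts), max(ts)) if ts else (None, None)
    w_start, w_end = window

    episodes: list[tuple] = []
    ordered = sorted(alarms, key=lambda p: (p.timestamp, p.row_index))
    consumed: set[int] = set()
    for i, end_ev in enumerate(ordered):
        if end_ev.event.status != "ended":
            continue
        key = _key(end_ev)
        match = None
        for j in range(i - 1, -1, -1):
            cand = ordered[j]
            if (cand.row_index not in consumed
                    and cand.event.status == "generated"
                    and _key(cand) == key):
                match = cand
                break
        if match is None:
            for j in range(i + 1, len(ordered)):
                cand = ordered[j]
                if (cand.row_index not in consumed
                        and cand.event.status == "generated"
                        and _key(cand) == key
                        and cand.timestamp == end_ev.timestamp):
                    match = cand
                    break
            if match is not None:
                consumed.add(match.row_index)
                consumed.add(end_ev.row_index)
                episodes.append((key, match.timestamp, match.timestamp,
                                 0.0, False, False))
                continue
        if match is None:
            consumed.add(end_ev.row_index)
            episodes.append((key, w_start, end_ev.timestamp,
                             max((end_ev.timestamp - w_start).total_seconds(),
                                 0.0),
                             True, False))
            continue
        consumed.add(match.row_index)
        consumed.add(end_ev.row_index)
        episodes.append((key, match.timestamp, end_ev.timestamp,
                         (end_ev.timestamp - match.timestamp).total_seconds(),
                         False, False))
    for p in ordered:
        if p.row_index not in consumed and p.event.status == "generated":
            episodes.append((_key(p), p.timestamp, w_end,
                             max((w_end - p.timestamp).total_seconds(), 0.0),
                             False, True))
    return episodes


def episodes_as_tuples(result) -> list[tuple]:
    return [((e.key.patient, e.key.bed_label, e.key.device_name,
              e.key.parameter, e.key.priority_marks),
             e.start_ts, e.end_ts, e.duration_s,
             e.left_censored, e.right_censored)
            for e in result.episodes]


def brute_force_announced(active) -> set[int]:
    """Declarative evaluation of the announcement ordering rules.

    An alarm is announced iff it is live and unacknowledged, its
    severity equals the top severity among live unacknowledged alarms,
    and no other live unacknowledged alarm in the same chain strictly
    beats it on (severity, onset, id).  Alarms outside the three chains
    compete only with themselves.
    """
    from alarmaudit.chain import severity_rank

    live = [a for a in active
            if (a.condition_active or (a.latching and not a.acknowledged))
            and not a.acknowledged
            and a.severity_class != "soft_inop"]
    if not live:
        return set()
    top = max(severity_rank(a) for a in live)
    announced = set()
    for a in live:
        if severity_rank(a) != top:
            continue
        beaten = any(
            b is not a and b.chain == a.chain and a.chain != "none"
            and (severity_rank(b), b.onset_ts, b.alarm_id)
            > (severity_rank(a), a.onset_ts, a.alarm_id)
            for b in live)
        if not beaten:
            announced.add(a.alarm_id)
    return announced
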