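"""Glue between raw rows and typed events: parse a whole log at once."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

from .grammar import ParsedEvent, UnparsedEvent, parse_message
from .records import AuditRecord
from .registry import DEFAULT_REGISTRY, Registry

__all__ = ["ParsedRecord", "parse_records", "unparsed_records"]


@dataclass(frozen=True)
class ParsedRecord:
    """An audit-log row together with its parsed event."""

    record: AuditRecord
    event: ParsedEvent

    @property
    def timestamp(self) -> datetime:
        return self.record.timestamp

    @property
    def row_index(self) -> int:
        return self.record.row_index


def parse_records(records: Iterable[AuditRecord],
                  registry: Registry = DEFAULT_REGISTRY,
                  strict: bool = False) -> list[ParsedRecord]:
    """Parse every row's message; file order is preserved.

    In lenient mode (default) unrecognized messages come back as
    :class:`UnparsedEvent` entries; ``strict=True`` raises on the first
    one, naming the offending row.
    """
    out: list[ParsedRecord] = []
    for rec in records:
        event = parse_message(rec.raw_message, registry)
        if strict and isinstance(event, UnparsedEvent):
            raise ValueError(
                f"row {rec.row_index}: unparseable message {rec.raw_message!r}")
        out.append(ParsedRecord(rec, event))
    return out


def unparsed_records(parsed: Sequence[ParsedRecord]) -> list[ParsedRecord]:
    return [p for p in parsed if isinstance(p.event, UnparsedEvent)]
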