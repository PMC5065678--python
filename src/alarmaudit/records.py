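"""Core record type for one raw audit-log row.

A central-station audit log is a chronological table with five columns:
the event timestamp, the bed label, the (usually masked) medical record
number, the free-text "Alarm and Action" message, and the Information
Center host ("device") name.  Everything downstream — message parsing,
episode pairing, rate reports, safety audits — starts from this row type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from datetime import datetime

__all__ = ["AuditRecord", "parse_timestamp", "clean_message", "MASKED_MRN_RE"]

#: MRNs exported from clinical systems are frequently masked to all zeros
#: for confidentiality; such values carry no patient identity.
MASKED_MRN_RE = re.compile(r"^0+$")

# Vendor exports come out of spreadsheets and sometimes through word
# processors; these artifacts are annotation noise, not device output.
_FOOTNOTE_RE = re.compile(r"\^[A-Za-z0-9]{1,3}\^")
_SMART_QUOTES = str.maketrans({"‘": "'", "’": "'", "“": '"', "”": '"'})

_TS_FORMATS = (
    "%m/%d/%y %H:%M:%S",
    "%m/%d/%y %H:%M",
    "%m/%d/%Y %H:%M:%S",
    "%m/%d/%Y %H:%M",
    "%Y-%m-%dT%H:%M:%S",
    "%Y-%m-%d %H:%M:%S",
    "%Y-%m-%dT%H:%M",
    "%Y-%m-%d %H:%M",
)


def parse_timestamp(text: str) -> datetime:
    """Parse an audit-log timestamp to second resolution.

    Accepts the vendor's ``M/D/YY H:MM:SS`` and ``M/D/YY H:MM`` forms
    (missing seconds read as ``:00``) as well as ISO-8601.  Two-digit
    years pivot to 2000-2099: the logging devices postdate 2000, so a
    two-digit year can only mean this century.
    """
    text = text.strip()
    for fmt in _TS_FORMATS:
        try:
            ts = datetime.strptime(text, fmt)
        except ValueError:
            continue
        if "%y " in fmt and ts.year < 2000:
            ts = ts.replace(year=ts.year + 100)
        return ts
    raise ValueError(f"unparseable timestamp: {text!r}")


def clean_message(text: str) -> str:
    """Normalize a raw "Alarm and Action" cell.

    Strips embedded ``^x^`` footnote markers (annotation noise that can
    survive copy/paste from formatted documents), normalizes smart quotes
    and the Unicode minus sign to ASCII, and trims whitespace.
    """
    text = _FOOTNOTE_RE.sub("", text)
    text = text.translate(_SMART_QUOTES)
    text = text.replace("−", "-")  # Unicode minus
    text = re.sub(r"\s+", " ", text)
    return text.strip()


@dataclass(frozen=True)
class AuditRecord:
    """One raw audit-log row, timestamp normalized and message cleaned.

    Attributes
    ----------
    timestamp : datetime
        Event time at minute or second resolution.
    bed_label : str
        Bed identifier, e.g. ``"9115-S1"``.
    mrn : str
        Medical record number; may be masked (all zeros).
    raw_message : str
        The "Alarm and Action" cell after cleaning.
    device_name : str
        Information Center host, e.g. ``"PIIC iX: ixsurv006"``.
    row_index : int
        Zero-based position in the source file; preserves file order,
        which matters because the log is chronological and same-second
        events are only ordered by row position.
    """

    timestamp: datetime
    bed_label: str
    mrn: str
    raw_message: str
    device_name: str
    row_index: int

    def __post_init__(self) -> None:
        if not self.bed_label:
            raise ValueError("bed_label must be non-empty")
        if not self.raw_message.strip():
            raise ValueError("raw_message must be non-empty")

    @property
    def mrn_is_masked(self) -> bool:
        return bool(MASKED_MRN_RE.match(self.mrn)) or not self.mrn

    @property
    def patient_key(self) -> str:
        """Identity for grouping: the MRN, or bed+device when masked."""
        if self.mrn_is_masked:
            return f"{self.bed_label}|{self.device_name}"
        return self.mrn

    def with_row_index(self, idx: int) -> "AuditRecord":
        return replace(self, row_index=idx)
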