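"""Read and write audit-log export files.

The central station exports the unit audit log as a spreadsheet
(columns Date / Bed label / MRN / Alarm and Action / Device name);
sites re-save it as CSV or TSV with locally varying delimiters,
headers, and encodings, so the reader sniffs the dialect and maps
headers permissively.  The MRN column is optional — some exports omit
it.  Timestamps come as ``M/D/YY H:MM:SS`` or ``M/D/YY H:MM`` (missing
seconds read as ``:00``).

``write_normalized`` emits one canonical CSV dialect: header
``date,bed_label,mrn,message,device_name`` with ISO-8601 timestamps.
Writing then reading is the identity on all five fields.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from pathlib import Path
from typing import BinaryIO, Iterable, Optional, Sequence, Union

from .records import AuditRecord, clean_message, parse_timestamp

__all__ = ["read_audit_log", "write_normalized", "CANONICAL_HEADER"]

log = logging.getLogger(__name__)

CANONICAL_HEADER = ("date", "bed_label", "mrn", "message", "device_name")

_HEADER_SYNONYMS = {
    "date": "date", "timestamp": "date", "time": "date", "datetime": "date",
    "bed label": "bed_label", "bed_label": "bed_label", "bed": "bed_label",
    "mrn": "mrn", "medical record number": "mrn",
    "alarm and action": "message", "message": "message",
    "alarm_and_action": "message", "raw_message": "message",
    "device name": "device_name", "device_name": "device_name",
    "device": "device_name",
}

_XLSX_MAGIC = b"PK\x03\x04"


def _decode(data: bytes) -> str:
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;|").delimiter
    except csv.Error:
        return ","


def _normalize_header(cell: str) -> Optional[str]:
    return _HEADER_SYNONYMS.get(clean_message(cell).lower().rstrip(":"))


def _map_columns(first_row: Sequence[str]) -> Optional[dict[str, int]]:
    """Map canonical field -> column index from a header row, or None if
    the row does not look like a header."""
    mapping: dict[str, int] = {}
    for i, cell in enumerate(first_row):
        name = _normalize_header(cell)
        if name is not None and name not in mapping:
            mapping[name] = i
    if "date" in mapping and "message" in mapping:
        return mapping
    return None


def _positional_mapping(width: int) -> dict[str, int]:
    if width >= 5:
        return {"date": 0, "bed_label": 1, "mrn": 2, "message": 3,
                "device_name": 4}
    if width == 4:  # MRN column omitted
        return {"date": 0, "bed_label": 1, "message": 2, "device_name": 3}
    raise ValueError(
        f"cannot identify columns: expected >= 4 columns, got {width}")


def _rows_from_xlsx(data: bytes, sheet: int) -> list[list[str]]:
    from openpyxl import load_workbook  # deferred: costly import

    wb = load_workbook(_io.BytesIO(data), read_only=True, data_only=True)
    ws = wb.worksheets[sheet]
    return [["" if c is None else str(c) for c in row]
            for row in ws.iter_rows(values_only=True)]


def _rows_from_text(text: str, delimiter: Optional[str]) -> list[list[str]]:
    if delimiter is None:
        delimiter = _sniff_delimiter(text[:4096])
    reader = csv.reader(_io.StringIO(text), delimiter=delimiter)
    return [row for row in reader if any(cell.strip() for cell in row)]


def read_audit_log(source: Union[str, Path, BinaryIO],
                   dialect: Optional[str] = None,
                   *, sheet: int = 0,
                   errors: str = "strict",
                   deduplicate: bool = False) -> list[AuditRecord]:
    """Read an audit-log export into :class:`AuditRecord` rows.

    Parameters
    ----------
    source
        Path to a CSV/TSV/XLSX export, or a binary stream.
    dialect
        Optional delimiter hint for text files (e.g. ``","`` or
        ``"\\t"``); sniffed when omitted.  Ignored for XLSX.
    sheet
        Worksheet index for XLSX input (first sheet by default).
    errors
        ``"strict"`` raises on a row with an unparseable timestamp,
        naming the row; ``"skip"`` logs and drops such rows.
    deduplicate
        Drop consecutive byte-identical rows.  Off by default: devices
        may legitimately emit duplicate rows.
    """
    if errors not in ("strict", "skip"):
        raise ValueError("errors must be 'strict' or 'skip'")
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            data = path.read_bytes()
        except OSError as exc:
            raise IOError(f"cannot read audit log {path}: {exc}") from exc
    else:
        data = source.read()

    if data.startswith(_XLSX_MAGIC):
        rows = _rows_from_xlsx(data, sheet)
    else:
        rows = _rows_from_text(_decode(data), dialect)
    if not rows:
        raise ValueError("audit log has no rows at all (not even a header)")

    mapping = _map_columns(rows[0])
    data_rows = rows[1:] if mapping is not None else rows
    records: list[AuditRecord] = []
    prev_row: Optional[list[str]] = None
    for i, row in enumerate(data_rows):
        if deduplicate and row == prev_row:
            continue
        prev_row = list(row)
        cols = mapping if mapping is not None else _positional_mapping(len(row))

        def cell(name: str) -> str:
            idx = cols.get(name)
            return row[idx].strip() if idx is not None and idx < len(row) else ""

        try:
            ts = parse_timestamp(cell("date"))
        except ValueError as exc:
            if errors == "strict":
                raise ValueError(f"row {i + 1}: {exc}") from exc
            log.warning("skipping row %d: %s", i + 1, exc)
            continue
        records.append(AuditRecord(
            timestamp=ts,
            bed_label=clean_message(cell("bed_label")),
            mrn=clean_message(cell("mrn")),
            raw_message=clean_message(cell("message")),
            device_name=clean_message(cell("device_name")),
            row_index=len(records),
        ))
    return records


def write_normalized(records: Iterable[AuditRecord],
                     sink: Union[str, Path]) -> None:
    """Write records as canonical CSV; output is byte-stable per input."""
    path = Path(sink)
    try:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(CANONICAL_HEADER)
            for rec in records:
                writer.writerow([
                    rec.timestamp.isoformat(),
                    rec.bed_label,
                    rec.mrn,
                    rec.raw_message,
                    rec.device_name,
                ])
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
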