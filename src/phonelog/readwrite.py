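"""Canonical plain-text schema for event logs.

Every export ultimately decrypts to one table: ``timestamp,event,app``
— integer UNIX milliseconds, the event-type name, and the app package
identifier (empty for device-level events). Standard CSV quoting applies,
so package names containing commas survive a round trip.
"""

from __future__ import annotations

import csv
import io
from os import PathLike
from typing import TextIO

from .events import EventStream, EventType, RowRejection, UsageEvent, validate_stream

__all__ = [
    "CSV_HEADER",
    "LogFormatError",
    "write_log_csv",
    "read_log_csv",
    "stream_to_csv_text",
    "stream_from_csv_text",
]

CSV_HEADER = ("timestamp", "event", "app")


class LogFormatError(Exception):
    """File does not conform to the canonical log schema."""


def _write(stream: EventStream, fh: TextIO) -> None:
    w = csv.writer(fh, lineterminator="\n")
    w.writerow(CSV_HEADER)
    for ev in stream.events:
        w.writerow([ev.timestamp_ms, ev.type.value, ev.app_id or ""])


def write_log_csv(stream: EventStream, path: str | PathLike) -> None:
    """Write a validated stream to ``path`` in the canonical schema."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write(stream, fh)


def stream_to_csv_text(stream: EventStream) -> str:
    """The canonical CSV as a string (what gets encrypted on export)."""
    buf = io.StringIO()
    _write(stream, buf)
    return buf.getvalue()


def _read(fh: TextIO, source: str) -> tuple[EventStream, list[RowRejection]]:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise LogFormatError("missing header") from None
    if tuple(h.strip() for h in header) != CSV_HEADER:
        raise LogFormatError(
            f"missing or wrong header: expected {','.join(CSV_HEADER)}"
        )
    events: list[UsageEvent] = []
    rejections: list[RowRejection] = []
    for i, row in enumerate(reader, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 3:
            rejections.append(RowRejection(i, f"expected 3 fields, got {len(row)}", row))
            continue
        ts_s, type_s, app_s = row
        try:
            ts = int(ts_s)
        except ValueError:
            rejections.append(RowRejection(i, "non-integer timestamp", row))
            continue
        try:
            etype = EventType(type_s.strip())
        except ValueError:
            rejections.append(RowRejection(i, f"unknown event type {type_s.strip()!r}", row))
            continue
        events.append(UsageEvent(ts, etype, app_s or None, source=source))
    validated, more = validate_stream(EventStream(events, source=source))
    return validated, rejections + more


def read_log_csv(
    path: str | PathLike, source: str = "continuous"
) -> tuple[EventStream, list[RowRejection]]:
    """Read and validate a canonical log CSV.

    Unknown event labels and malformed timestamps reject that row only;
    the rest of the file is kept. A header-only file yields an empty
    stream. A missing/wrong header raises :class:`LogFormatError`.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _read(fh, source)


def stream_from_csv_text(
    text: str, source: str = "continuous"
) -> tuple[EventStream, list[RowRejection]]:
    """Parse canonical CSV text (e.g. a decrypted export payload)."""
    return _read(io.StringIO(text), source)
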