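"""Reading-log CSV ingest and export.

Dialect (RFC-4180): header ``timestamp,value_mgdl,tag,bolus_given,carbs_logged``;
ISO-8601 local timestamps; booleans ``true``/``false`` or empty for unknown.
mmol/L logs are converted to mg/dL at ingest (factor 18.016) and never later.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from .core import DataError, GlucoseReading, MMOL_TO_MGDL, Tag

logger = logging.getLogger(__name__)

HEADER = ["timestamp", "value_mgdl", "tag", "bolus_given", "carbs_logged"]


class IngestError(DataError):
    """Malformed input log; the message carries the offending row number."""


def _parse_bool(s: str, row: int) -> Union[bool, None]:
    s = s.strip().lower()
    if s == "":
        return None
    if s == "true":
        return True
    if s == "false":
        return False
    raise IngestError(f"row {row}: boolean field must be true/false/empty, got {s!r}")


def read_readings_csv(
    source: Union[str, Path, TextIO], unit: str = "mgdl"
) -> list[GlucoseReading]:
    """Parse a readings CSV; rejects duplicate timestamps and invalid rows.

    ``unit="mmol"`` converts values to mg/dL on the way in.
    """
    if unit not in ("mgdl", "mmol"):
        raise ValueError(f"unit must be 'mgdl' or 'mmol', got {unit!r}")
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_readings_csv(fh, unit=unit)

    reader = csv.reader(source)
    try:
        header = next(reader)
    except StopIteration:
        raise IngestError("row 1: empty file, expected header") from None
    if [h.strip() for h in header] != HEADER:
        raise IngestError(
            f"row 1: bad header {header!r}, expected {','.join(HEADER)}"
        )

    readings: list[GlucoseReading] = []
    seen: dict[datetime, int] = {}
    for rownum, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(HEADER):
            raise IngestError(f"row {rownum}: expected {len(HEADER)} fields, got {len(row)}")
        ts_s, val_s, tag_s, bolus_s, carbs_s = (c.strip() for c in row)
        try:
            ts = datetime.fromisoformat(ts_s)
        except ValueError:
            raise IngestError(f"row {rownum}: invalid ISO-8601 timestamp {ts_s!r}") from None
        try:
            value = float(val_s)
        except ValueError:
            raise IngestError(f"row {rownum}: invalid glucose value {val_s!r}") from None
        if unit == "mmol":
            value *= MMOL_TO_MGDL
        try:
            tag = Tag(tag_s)
        except ValueError:
            raise IngestError(f"row {rownum}: unknown tag {tag_s!r}") from None
        if ts in seen:
            logger.error(
                "row %d: duplicate timestamp %s (first seen at row %d); rejected",
                rownum, ts_s, seen[ts],
            )
            raise IngestError(f"row {rownum}: duplicate timestamp {ts_s}")
        seen[ts] = rownum
        try:
            readings.append(
                GlucoseReading(
                    timestamp=ts,
                    value=value,
                    tag=tag,
                    bolus_given=_parse_bool(bolus_s, rownum),
                    carbs_logged=_parse_bool(carbs_s, rownum),
                )
            )
        except DataError as exc:
            raise IngestError(f"row {rownum}: {exc}") from None
    return sorted(readings, key=lambda r: r.timestamp)


def _fmt_bool(b: Union[bool, None]) -> str:
    return "" if b is None else ("true" if b else "false")


def write_readings_csv(
    readings: Iterable[GlucoseReading], dest: Union[str, Path, TextIO]
) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            write_readings_csv(readings, fh)
            return
    writer = csv.writer(dest, lineterminator="\n")
    writer.writerow(HEADER)
    for r in sorted(readings, key=lambda r: r.timestamp):
        writer.writerow(
            [
                r.timestamp.isoformat(timespec="minutes"),
                f"{r.value:g}",
                r.tag.value,
                _fmt_bool(r.bolus_given),
                _fmt_bool(r.carbs_logged),
            ]
        )


def readings_to_csv_text(readings: Iterable[GlucoseReading]) -> str:
    buf = _io.StringIO()
    write_readings_csv(readings, buf)
    return buf.getvalue()
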