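"""Flat-CSV ingest and export.

Two files describe a cohort: ``sensor.csv`` with columns participant_id,
date (ISO-8601), start_min, end_min, dose_jm2 and ``reports.csv`` with
participant_id, date, start_min, end_min, activity.  Times are integer
minutes since local midnight.  Malformed rows are collected, with line
numbers and reasons, rather than aborting the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .preprocessing import DayRecord
from .timeline import Interval, SelfReport, SensorReading

SENSOR_COLUMNS = ["participant_id", "date", "start_min", "end_min", "dose_jm2"]
REPORT_COLUMNS = ["participant_id", "date", "start_min", "end_min", "activity"]


@dataclass
class RejectedRow:
    path: str
    line: int  # 1-based line number in the CSV (header is line 1)
    reason: str


@dataclass
class IngestResult:
    days: list[DayRecord]
    rejected: list[RejectedRow] = field(default_factory=list)
    n_rows_read: int = 0

    @property
    def n_rows_kept(self) -> int:
        return self.n_rows_read - len(self.rejected)


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "date": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_events(sensor_path: str | Path, reports_path: str | Path) -> IngestResult:
    """Read both streams into validated day records.

    Rows with end <= start, out-of-range times, negative dose, or intervals
    overlapping an earlier-accepted row of the same stream and day are
    rejected with a reason; everything else is grouped by (participant,
    date).
    """
    result = IngestResult(days=[])
    sensor_df = _read_table(sensor_path, SENSOR_COLUMNS)
    report_df = _read_table(reports_path, REPORT_COLUMNS)
    result.n_rows_read = len(sensor_df) + len(report_df)

    readings: dict[tuple[str, str], list[SensorReading]] = {}
    reports: dict[tuple[str, str], list[SelfReport]] = {}

    def accept_interval(row, path, line) -> Interval | None:
        try:
            return Interval(int(row.start_min), int(row.end_min))
        except (ValueError, TypeError) as exc:
            result.rejected.append(RejectedRow(str(path), line, str(exc)))
            return None

    for idx, row in enumerate(sensor_df.itertuples(index=False)):
        line = idx + 2
        iv = accept_interval(row, sensor_path, line)
        if iv is None:
            continue
        try:
            reading = SensorReading(iv, float(row.dose_jm2))
        except (ValueError, TypeError) as exc:
            result.rejected.append(RejectedRow(str(sensor_path), line, str(exc)))
            continue
        key = (str(row.participant_id), str(row.date))
        bucket = readings.setdefault(key, [])
        if any(iv.start < r.interval.end and r.interval.start < iv.end
               for r in bucket):
            result.rejected.append(RejectedRow(
                str(sensor_path), line, f"overlaps another sensor row: {iv}"))
            continue
        bucket.append(reading)

    for idx, row in enumerate(report_df.itertuples(index=False)):
        line = idx + 2
        iv = accept_interval(row, reports_path, line)
        if iv is None:
            continue
        key = (str(row.participant_id), str(row.date))
        bucket = reports.setdefault(key, [])
        if any(iv.start < r.interval.end and r.interval.start < iv.end
               for r in bucket):
            result.rejected.append(RejectedRow(
                str(reports_path), line, f"overlaps another self-report: {iv}"))
            continue
        activity = "" if pd.isna(row.activity) else str(row.activity)
        bucket.append(SelfReport(iv, activity))

    for key in sorted(set(readings) | set(reports)):
        pid, date = key
        result.days.append(DayRecord(
            participant_id=pid, date=date,
            self_reports=tuple(reports.get(key, ())),
            sensor_readings=tuple(readings.get(key, ())),
        ))
    return result


def write_events(
    days: Sequence[DayRecord], sensor_path: str | Path, reports_path: str | Path
) -> None:
    """Write day records back to the two-CSV schema (inverse of
    :func:`read_events` for well-formed data)."""
    sensor_rows = [
        {"participant_id": d.participant_id, "date": d.date,
         "start_min": r.interval.start, "end_min": r.interval.end,
         "dose_jm2": r.dose}
        for d in days for r in d.sensor_readings
    ]
    report_rows = [
        {"participant_id": d.participant_id, "date": d.date,
         "start_min": r.interval.start, "end_min": r.interval.end,
         "activity": r.activity}
        for d in days for r in d.self_reports
    ]
    pd.DataFrame(sensor_rows, columns=SENSOR_COLUMNS).to_csv(
        sensor_path, index=False)
    pd.DataFrame(report_rows, columns=REPORT_COLUMNS).to_csv(
        reports_path, index=False)
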