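"""Per-day pre-analysis filters.

Each participant-day is filtered to the 6am-6pm analysis window (outside it
ambient UV is too weak to matter), self-reports shorter than the 15-minute
reporting minimum are dropped, and days are classified as valid, sensor-less
or "true zero" before metric aggregation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .timeline import (
    Config,
    Interval,
    SelfReport,
    SensorEvent,
    SensorReading,
    overlap_minutes,
)


class DayStatus(enum.Enum):
    VALID = "valid"
    NO_SENSOR_DATA = "no_sensor_data"
    TRUE_ZERO = "true_zero"


@dataclass(frozen=True)
class DayRecord:
    """One participant-day: the self-report stream and the sensor stream.

    ``sensor_events`` is populated by the clustering stage; until then it is
    ``None``.  Within each stream, intervals must not overlap (overlapping
    raw self-reports are an ingest error, checked at read time).
    """

    participant_id: str
    date: str
    self_reports: tuple[SelfReport, ...] = ()
    sensor_readings: tuple[SensorReading, ...] = ()
    sensor_events: Optional[tuple[SensorEvent, ...]] = None
    status: DayStatus = DayStatus.VALID
    worn: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "self_reports",
            tuple(sorted(self.self_reports, key=lambda r: r.interval)))
        object.__setattr__(
            self, "sensor_readings",
            tuple(sorted(self.sensor_readings, key=lambda r: r.interval)))
        if self.sensor_events is not None:
            object.__setattr__(
                self, "sensor_events",
                tuple(sorted(self.sensor_events, key=lambda e: e.interval)))

    @property
    def report_minutes(self) -> int:
        return sum(r.interval.duration for r in self.self_reports)

    @property
    def reading_minutes(self) -> int:
        return sum(r.interval.duration for r in self.sensor_readings)


def check_non_overlapping(intervals: Sequence[Interval]) -> None:
    """Raise ``ValueError`` if any two intervals in a stream overlap."""
    ordered = sorted(intervals)
    for a, b in zip(ordered, ordered[1:]):
        if overlap_minutes(a, b) > 0:
            raise ValueError(f"overlapping intervals in one stream: {a} and {b}")


def _clip_report(report: SelfReport, cfg: Config) -> Optional[SelfReport]:
    clipped = report.interval.clip(cfg.window_start, cfg.window_end)
    if clipped is None:
        return None
    return SelfReport(clipped, report.activity)


def _clip_reading(reading: SensorReading, cfg: Config) -> Optional[SensorReading]:
    # Straddling readings are trimmed to whole 6-min slots inside the window
    # (slots counted from the reading's own start) so the quantization
    # invariant survives; dose is prorated by the retained fraction.
    iv = reading.interval
    if iv.end <= cfg.window_start or iv.start >= cfg.window_end:
        return None
    if iv.start >= cfg.window_start and iv.end <= cfg.window_end:
        return reading
    q = cfg.quantum
    n = iv.duration // q
    kept = [k for k in range(n)
            if iv.start + k * q >= cfg.window_start
            and iv.start + (k + 1) * q <= cfg.window_end]
    if not kept:
        return None
    new_iv = Interval(iv.start + kept[0] * q, iv.start + (kept[-1] + 1) * q)
    return SensorReading(new_iv, reading.dose * len(kept) / n)


def filter_to_window(day: DayRecord, cfg: Config) -> DayRecord:
    """Remove events entirely outside the analysis window; clip straddlers.

    Events ending at or before ``window_start`` or starting at or after
    ``window_end`` are removed outright; boundary-straddling events are kept
    and clipped so minute metrics stay confined to the 720-minute window.
    """
    reports = tuple(r for r in (_clip_report(r, cfg) for r in day.self_reports)
                    if r is not None)
    readings = tuple(r for r in (_clip_reading(r, cfg) for r in day.sensor_readings)
                     if r is not None)
    return replace(day, self_reports=reports, sensor_readings=readings)


def filter_short_selfreports(day: DayRecord, cfg: Config) -> DayRecord:
    """Drop self-reports shorter than the reporting minimum (15 min); such
    reports are inconsistent with the study instructions.  The sensor stream
    is untouched."""
    kept = tuple(r for r in day.self_reports
                 if r.interval.duration >= cfg.min_report_duration)
    return replace(day, self_reports=kept)


def validate_day(day: DayRecord) -> DayRecord:
    """Assign the day's analysis status.

    ``no_sensor_data`` when self-reports exist but the sensor stream is empty
    and the day is flagged non-worn by the caller (non-wear is an input flag,
    not inferred); ``true_zero`` when both streams are empty; ``valid``
    otherwise.  Non-valid days are excluded from metric aggregation.
    """
    has_sensor = bool(day.sensor_readings)
    has_reports = bool(day.self_reports)
    if not has_sensor and not has_reports:
        status = DayStatus.TRUE_ZERO
    elif not has_sensor and has_reports and not day.worn:
        status = DayStatus.NO_SENSOR_DATA
    else:
        status = DayStatus.VALID
    return replace(day, status=status)


def preprocess_day(day: DayRecord, cfg: Config) -> DayRecord:
    """Window filter, short-report filter, then status validation."""
    return validate_day(filter_short_selfreports(filter_to_window(day, cfg), cfg))


def preprocess(days: Sequence[DayRecord], cfg: Config) -> list[DayRecord]:
    return [preprocess_day(d, cfg) for d in days]
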