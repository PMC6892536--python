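"""Core interval types and arithmetic shared by every pipeline stage.

All times are integer minutes since local midnight; intervals are half-open
``[start, end)`` so that adjacent 6-minute sensor slots do not overlap and
minute counting is exact.  A single local time zone is assumed and events
never cross midnight (the analysis window is 6am-6pm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

MINUTES_PER_DAY = 1440

#: Logging quantum of the wearable UV dosimeter (minutes).
QUANTUM = 6


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open span ``[start, end)`` in minutes since local midnight."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= MINUTES_PER_DAY):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need "
                f"0 <= start < end <= {MINUTES_PER_DAY}"
            )

    @property
    def duration(self) -> int:
        return self.end - self.start

    def clip(self, lo: int, hi: int) -> Optional["Interval"]:
        """Intersection with ``[lo, hi)``, or ``None`` if empty."""
        s, e = max(self.start, lo), min(self.end, hi)
        return Interval(s, e) if s < e else None


@dataclass(frozen=True)
class SensorReading:
    """Raw dosimeter log entry: a 6-minute-quantized exposure interval with
    accumulated UV dose in J/m^2."""

    interval: Interval
    dose: float

    def __post_init__(self) -> None:
        if self.interval.duration % QUANTUM != 0:
            raise ValueError(
                f"sensor reading duration {self.interval.duration} is not a "
                f"multiple of {QUANTUM} minutes"
            )
        if self.dose < 0:
            raise ValueError(f"negative UV dose {self.dose}")


@dataclass(frozen=True)
class SelfReport:
    """A participant-recalled outdoor interval with a free-text activity
    label.  Durations below the 15-minute reporting minimum may appear here
    before pre-filtering."""

    interval: Interval
    activity: str = ""


@dataclass(frozen=True)
class SensorEvent:
    """Clustered exposure event: spans its constituent readings, carries
    their summed dose and the number of merged fragments."""

    interval: Interval
    dose: float
    n_fragments: int = 1

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"negative UV dose {self.dose}")
        if self.n_fragments < 1:
            raise ValueError("a sensor event contains at least one reading")


@dataclass(frozen=True)
class Config:
    """Analysis thresholds.

    Defaults follow the study protocol: a 6am-6pm analysis window, 15-minute
    minimum reportable activity, 6-minute dosimeter quantum, fragment-merge
    separation tau_mds of 6 minutes, a 60-minute alignment bounding box, a
    30-minute over/under-reporting day threshold, and 10am-4pm peak hours.
    """

    window_start: int = 360
    window_end: int = 1080
    min_report_duration: int = 15
    quantum: int = QUANTUM
    tau_mds: int = 6
    bounding_box: int = 60
    day_discrepancy_threshold: int = 30
    # "at least 30 minutes" => inclusive comparison; set False for strict >.
    day_threshold_inclusive: bool = True
    peak_start: int = 600
    peak_end: int = 960

    def __post_init__(self) -> None:
        positive = (
            self.window_start, self.window_end, self.min_report_duration,
            self.quantum, self.tau_mds, self.bounding_box,
            self.day_discrepancy_threshold, self.peak_start, self.peak_end,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all Config thresholds must be positive")
        if not self.window_start < self.window_end <= MINUTES_PER_DAY:
            raise ValueError("require window_start < window_end <= 1440")
        if not (self.window_start <= self.peak_start < self.peak_end
                <= self.window_end):
            raise ValueError("peak window must lie within the analysis window")


def overlap_minutes(a: Interval, b: Interval) -> int:
    """Length of the intersection of two intervals; 0 when disjoint."""
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_minutes(a: Interval, b: Interval) -> int:
    """Length of the empty span between two intervals.

    0 when they overlap or touch; symmetric in its arguments.  This is the
    separation distance used both for fragment merging (tau_mds) and for the
    alignment bounding box.
    """
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def quantize_duration_up(raw_minutes: int) -> int:
    """Round a duration up to the closest multiple of the 6-minute quantum,
    mirroring how the dosimeter reports exposure minutes."""
    if raw_minutes < 0:
        raise ValueError(f"negative duration {raw_minutes}")
    return -(-raw_minutes // QUANTUM) * QUANTUM
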