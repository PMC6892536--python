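"""Agreement metrics between self-reports and sensor events.

Minute-level metrics treat the dosimeter as ground truth inside the 6am-6pm
window: true-positive minutes are reported and sensed, false positives
reported only (over-reporting), false negatives sensed only
(under-reporting), and the Jaccard coefficient TP / (TP + FP + FN)
summarizes agreement.  Event-level metrics count whole reports/events with
or without a counterpart, with sub-counts for peak hours (10am-4pm starts)
and for exposures longer than 30 minutes.  Days are classified over- or
under-reported when the signed self-report minus sensor minute total crosses
the 30-minute threshold.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .alignment import AlignedDay
from .timeline import Config, Interval, SelfReport, overlap_minutes

DURATION_BINS = ("15-29 min", "30-59 min", "1-2 h", "2-3 h", ">3 h")
_BIN_EDGES = (15, 30, 60, 120, 180)


@dataclass(frozen=True)
class MinuteMetrics:
    tp_minutes: int
    fp_minutes: int
    fn_minutes: int

    @property
    def jaccard(self) -> Optional[float]:
        """TP / (TP + FP + FN); ``None`` (undefined) on an empty day."""
        denom = self.tp_minutes + self.fp_minutes + self.fn_minutes
        return self.tp_minutes / denom if denom > 0 else None


@dataclass(frozen=True)
class EventMetrics:
    """Whole-event counts: a self-report is a true positive iff it has
    matched minutes (> 0, overlap + flow); a sensor event with no matched
    minutes is a false negative.  Peak membership is by event start time in
    [10am, 4pm); the long-exposure sub-count requires strictly more than 30
    minutes."""

    tp_selfreports: int
    fp_selfreports: int
    fn_sensorevents: int
    tp_selfreports_peak: int
    fp_selfreports_peak: int
    fn_sensorevents_peak: int
    tp_selfreports_peak_over30: int
    fp_selfreports_peak_over30: int
    fn_sensorevents_peak_over30: int


class DayLabel(enum.Enum):
    OVER_REPORTED = "over_reported"
    UNDER_REPORTED = "under_reported"
    EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class DayClassification:
    label: DayLabel
    discrepancy_minutes: int  # signed: self-report total - sensor total


@dataclass(frozen=True)
class HistogramCell:
    start_hour: int
    duration_bin: str
    count: int


def minute_metrics(aligned: AlignedDay) -> MinuteMetrics:
    """Post-alignment minute tallies of an aligned day."""
    return MinuteMetrics(aligned.tp_after, aligned.fp_after, aligned.fn_after)


def overlap_minute_metrics(
    reports: Sequence[SelfReport], sensor_intervals: Sequence[Interval]
) -> MinuteMetrics:
    """Overlap-only minute tallies, used for the pre-alignment pipeline
    stages where the sensor stream is raw readings or intermediate events."""
    sr_total = sum(r.interval.duration for r in reports)
    se_total = sum(iv.duration for iv in sensor_intervals)
    tp = sum(overlap_minutes(r.interval, iv)
             for r in reports for iv in sensor_intervals)
    return MinuteMetrics(tp, sr_total - tp, se_total - tp)


def _in_peak(interval: Interval, cfg: Config) -> bool:
    return cfg.peak_start <= interval.start < cfg.peak_end


def event_metrics(aligned: AlignedDay, cfg: Config) -> EventMetrics:
    srs = aligned.residuals.self_reports
    ses = aligned.residuals.sensor_events

    def counts(items, matched_flags, want_matched):
        chosen = [it for it, m in zip(items, matched_flags) if m == want_matched]
        total = len(chosen)
        peak = [it for it in chosen if _in_peak(it.interval, cfg)]
        over30 = [it for it in peak if it.interval.duration > 30]
        return total, len(peak), len(over30)

    sr_matched = [aligned.sr_matched(i) > 0 for i in range(len(srs))]
    se_matched = [aligned.se_matched(j) > 0 for j in range(len(ses))]
    tp, tp_pk, tp_pk30 = counts(srs, sr_matched, True)
    fp, fp_pk, fp_pk30 = counts(srs, sr_matched, False)
    fn, fn_pk, fn_pk30 = counts(ses, se_matched, False)
    return EventMetrics(tp, fp, fn, tp_pk, fp_pk, fn_pk, tp_pk30, fp_pk30, fn_pk30)


def classify_day(aligned: AlignedDay, cfg: Config) -> DayClassification:
    """Signed discrepancy (self-report minutes minus sensor minutes) against
    the +-30-minute day threshold, inclusive by default."""
    disc = aligned.residuals.sr_total - aligned.residuals.se_total
    thr = cfg.day_discrepancy_threshold
    if cfg.day_threshold_inclusive:
        over, under = disc >= thr, disc <= -thr
    else:
        over, under = disc > thr, disc < -thr
    if over:
        label = DayLabel.OVER_REPORTED
    elif under:
        label = DayLabel.UNDER_REPORTED
    else:
        label = DayLabel.EQUIVALENT
    return DayClassification(label, disc)


def duration_bin(minutes: int) -> str:
    """Histogram bin for an event duration >= 15 min: [15,30), [30,60),
    [60,120), [120,180), [180, inf)."""
    if minutes < _BIN_EDGES[0]:
        raise ValueError(f"duration {minutes} below the 15-min reporting minimum")
    for edge, name in zip(_BIN_EDGES[1:], DURATION_BINS):
        if minutes < edge:
            return name
    return DURATION_BINS[-1]


def start_time_histogram(
    intervals: Sequence[Interval], cfg: Config
) -> list[HistogramCell]:
    """Counts of events by integer start hour (6..17) and duration bin; every
    (hour, bin) cell is emitted, zeros included."""
    counts: dict[tuple[int, str], int] = {}
    for iv in intervals:
        counts[(iv.start // 60, duration_bin(iv.duration))] = (
            counts.get((iv.start // 60, duration_bin(iv.duration)), 0) + 1)
    hours = range(cfg.window_start // 60, cfg.window_end // 60)
    return [HistogramCell(h, b, counts.get((h, b), 0))
            for h in hours for b in DURATION_BINS]


def paired_pre_post_test(
    pre: Sequence[float], post: Sequence[float]
) -> tuple[float, float]:
    """Paired two-sided t-test on post - pre differences.

    One value per participant (mean over that participant's valid days);
    degenerate input (n < 2, or identically zero differences) is an error
    rather than a silent zero.
    """
    if len(pre) != len(post):
        raise ValueError("pre and post samples must be paired (equal length)")
    if len(pre) < 2:
        raise ValueError("paired t-test needs at least two pairs")
    diffs = [b - a for a, b in zip(pre, post)]
    mean = sum(diffs) / len(diffs)
    if math.isclose(sum((d - mean) ** 2 for d in diffs), 0.0, abs_tol=1e-24):
        raise ValueError("zero variance in paired differences; t undefined")
    t, p = stats.ttest_rel(post, pre)
    if math.isnan(t):
        raise ValueError("t statistic undefined for these samples")
    return float(t), float(p)
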