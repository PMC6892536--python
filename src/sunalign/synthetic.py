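"""Seeded generator of ground-truth outdoor days seen through two channels.

A latent set of non-overlapping outdoor episodes per participant-day is
observed through (i) a sensor channel — 6-minute quantization, per-slot
dropout modelling body shading, which fragments episodes into runs of
surviving slots — and (ii) a recall channel — whole-event omission, a
Gaussian start-time offset (the event is remembered, its time misplaced),
spurious reports the sensor never saw, and a 15-minute minimum below which
episodes are never reported.

Default rates emulate a 10-day summer wear study of 37 adults: about 2.5
episodes per day averaging ~50 minutes (roughly 2.2 h of daily exposure),
mild sensor dropout, one-in-five recall omissions, quarter-hour-scale recall
offsets, and roughly one spurious report per five days.  UV dose follows a
deterministic diurnal bell peaking at noon so dose-conservation checks stay
exact.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocessing import DayRecord
from .timeline import Interval, SelfReport, SensorReading

_NOON = 720
_PLACEMENT_TRIES = 200


class SimulationError(RuntimeError):
    """Raised when a day cannot be packed with the requested events."""


@dataclass(frozen=True)
class SimulationParams:
    n_participants: int = 37
    n_days: int = 10
    #: Episodes per day: negative binomial (Poisson when dispersion == 0).
    events_per_day_mean: float = 2.5
    events_per_day_dispersion: float = 0.3
    #: Log-normal episode duration, minutes.
    duration_median: float = 40.0
    duration_sigma: float = 0.75
    #: Per-6-min-slot probability the sensor records nothing (body shading).
    sensor_dropout_prob: float = 0.1
    #: Probability a reportable episode is forgotten entirely.
    report_omission_prob: float = 0.15
    #: SD of the Gaussian start-time recall offset, minutes.
    report_offset_sd: float = 15.0
    #: Expected spurious self-reports per day (no matching exposure).
    spurious_report_rate: float = 0.2
    min_report_duration: int = 15
    #: Peak of the diurnal dose curve, J/m^2 per 6-min slot at solar noon.
    dose_rate_peak: float = 3.0
    window_start: int = 360
    window_end: int = 1080
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.sensor_dropout_prob, self.report_omission_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.duration_median <= 0 or self.duration_sigma < 0:
            raise ValueError("duration distribution must be positive")
        if self.spurious_report_rate < 0 or self.events_per_day_mean < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class TruthEvent:
    """Latent ground-truth outdoor episode both channels observe."""

    interval: Interval
    participant: str
    date: str


def dose_rate(minute: int, params: SimulationParams) -> float:
    """Deterministic diurnal UV dose per 6-min slot: cosine bell peaking at
    noon, zero outside the 6am-6pm half-period."""
    x = math.pi * (minute - _NOON) / 720.0
    return params.dose_rate_peak * max(0.0, math.cos(x))


def _draw_n_events(rng: np.random.Generator, params: SimulationParams) -> int:
    mean, disp = params.events_per_day_mean, params.events_per_day_dispersion
    if mean == 0:
        return 0
    if disp <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / disp
    return int(rng.negative_binomial(r, r / (r + mean)))


def _draw_duration(rng: np.random.Generator, params: SimulationParams) -> int:
    d = rng.lognormal(math.log(params.duration_median), params.duration_sigma)
    return max(5, int(round(d)))


def _place(
    rng: np.random.Generator,
    duration: int,
    occupied: list[Interval],
    lo: int,
    hi: int,
    margin: int = 0,
) -> Interval | None:
    """Uniform draw over every start position that fits ``duration`` into a
    free gap, at least ``margin`` minutes from anything occupied; ``None``
    only when no such position exists."""
    starts: list[range] = []
    cursor = lo
    for o in sorted(occupied):
        if (o.start - margin) - cursor >= duration:
            starts.append(range(cursor, o.start - margin - duration + 1))
        cursor = max(cursor, o.end + margin)
    if hi - cursor >= duration:
        starts.append(range(cursor, hi - duration + 1))
    total = sum(len(r) for r in starts)
    if total == 0:
        return None
    pick = int(rng.integers(0, total))
    for r in starts:
        if pick < len(r):
            return Interval(r[pick], r[pick] + duration)
        pick -= len(r)
    raise AssertionError("unreachable")


def generate_truth(params: SimulationParams) -> list[TruthEvent]:
    """Reproducible latent episodes for the whole cohort, sorted within day."""
    rng = np.random.default_rng(params.seed)
    events: list[TruthEvent] = []
    for p in range(params.n_participants):
        pid = f"P{p + 1:02d}"
        for d in range(params.n_days):
            date = (datetime.date(2017, 7, 1)
                    + datetime.timedelta(days=d)).isoformat()
            placed: list[Interval] = []
            for attempt in range(_PLACEMENT_TRIES):
                n = _draw_n_events(rng, params)
                placed = []
                for _ in range(n):
                    dur = _draw_duration(rng, params)
                    # episodes closer than one sensor quantum would be
                    # indistinguishable from a single episode: keep >= 6 min
                    # apart so quantized readings never collide
                    iv = _place(rng, dur, placed, params.window_start,
                                params.window_end, margin=6)
                    if iv is None:
                        break  # day over-full: redraw the whole day
                    placed.append(iv)
                else:
                    break
            else:
                raise SimulationError(
                    f"cannot pack the requested events into the "
                    f"{params.window_end - params.window_start}-min window "
                    f"({pid} {date}); lower events_per_day or durations")
            events.extend(TruthEvent(iv, pid, date) for iv in sorted(placed))
    return events


def observe_sensor(
    truth: Sequence[TruthEvent], params: SimulationParams,
    rng: np.random.Generator,
) -> list[SensorReading]:
    """Sensor channel for one day's truth events.

    Each episode is discretized into 6-min slots from its own start; each
    slot independently drops out with ``sensor_dropout_prob``; surviving
    consecutive runs become readings whose dose sums the diurnal rate over
    their slots.
    """
    readings: list[SensorReading] = []
    for ev in truth:
        n_slots = -(-ev.interval.duration // 6)
        keep = rng.random(n_slots) >= params.sensor_dropout_prob
        run_start = None
        for k in range(n_slots + 1):
            if k < n_slots and keep[k]:
                if run_start is None:
                    run_start = k
            elif run_start is not None:
                s = ev.interval.start + 6 * run_start
                e = ev.interval.start + 6 * k
                dose = sum(dose_rate(s + 6 * i + 3, params)
                           for i in range(k - run_start))
                readings.append(SensorReading(Interval(s, e), dose))
                run_start = None
    return sorted(readings, key=lambda r: r.interval)


def observe_selfreport(
    truth: Sequence[TruthEvent], params: SimulationParams,
    rng: np.random.Generator,
) -> list[SelfReport]:
    """Recall channel for one day's truth events.

    Episodes shorter than the 15-minute minimum are never reported; others
    are omitted with ``report_omission_prob`` or reported with their start
    shifted by a truncated Gaussian offset (duration preserved).  Spurious
    reports are added at ``spurious_report_rate`` per day.  Reports are kept
    mutually non-overlapping (the ingest contract) by redrawing colliding
    offsets, falling back to the true position, and as a last resort
    dropping the report.
    """
    reports: list[Interval] = []

    def try_add(iv: Interval) -> bool:
        if all(iv.end <= o.start or iv.start >= o.end for o in reports):
            reports.append(iv)
            return True
        return False

    for ev in truth:
        dur = ev.interval.duration
        if dur < params.min_report_duration:
            continue
        if rng.random() < params.report_omission_prob:
            continue
        added = False
        for _ in range(20):
            off = (int(round(rng.normal(0.0, params.report_offset_sd)))
                   if params.report_offset_sd > 0 else 0)
            start = min(max(ev.interval.start + off, 0), 1440 - dur)
            if try_add(Interval(start, start + dur)):
                added = True
                break
        if not added:
            try_add(ev.interval)  # fall back to perfect recall; else drop

    n_spurious = int(rng.poisson(params.spurious_report_rate)) \
        if params.spurious_report_rate > 0 else 0
    for _ in range(n_spurious):
        dur = max(params.min_report_duration, _draw_duration(rng, params))
        iv = _place(rng, dur, reports, params.window_start, params.window_end)
        if iv is not None:
            reports.append(iv)

    return [SelfReport(iv, activity="outdoor") for iv in sorted(reports)]


def simulate_cohort(params: SimulationParams) -> list[DayRecord]:
    """Full two-channel cohort as ingest-ready day records.

    A single seeded generator drives truth and both observation channels, so
    identical parameters (including the seed) give identical output.
    """
    truth = generate_truth(params)
    by_day: dict[tuple[str, str], list[TruthEvent]] = {}
    for p in range(params.n_participants):
        pid = f"P{p + 1:02d}"
        for d in range(params.n_days):
            date = (datetime.date(2017, 7, 1)
                    + datetime.timedelta(days=d)).isoformat()
            by_day[(pid, date)] = []
    for ev in truth:
        by_day[(ev.participant, ev.date)].append(ev)

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    days = []
    for (pid, date), evs in by_day.items():
        readings = observe_sensor(evs, params, rng)
        reports = observe_selfreport(evs, params, rng)
        days.append(DayRecord(
            participant_id=pid, date=date,
            self_reports=tuple(reports), sensor_readings=tuple(readings),
        ))
    return days
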