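from __future__ import annotations

import numpy as np
import pytest

from sunalign import (
    Config,
    DayRecord,
    Interval,
    SelfReport,
    SensorEvent,
    SensorReading,
    worked_example_day,
)


@pytest.fixture
def cfg() -> Config:
    return Config()


@pytest.fixture
def example_day() -> DayRecord:
    """Two self-reports (15, 60 min) vs two sensor events (18, 54 min),
    72 sensor minutes, no initial overlap."""
    return worked_example_day()


@pytest.fixture
def hand_clustering_day() -> DayRecord:
    """Six raw readings with hand-computed clustering outcomes.

    [600,606)+[612,618) merge to 18 min; [640,646) is an isolated 6-min
    reading (step 1 removes it); [700,712) survives step 1 but is a lone
    12-min event (step 3 removes it); [730,736)+[742,754) merge to 24 min.
    """
    doses = [1.5, 2.5, 0.5, 2.0, 1.0, 3.0]
    spans = [(600, 606), (612, 618), (640, 646), (700, 712), (730, 736),
             (742, 754)]
    return DayRecord(
        participant_id="H1", date="2017-07-02",
        sensor_readings=tuple(
            SensorReading(Interval(s, e), d) for (s, e), d in zip(spans, doses)),
        self_reports=(SelfReport(Interval(600, 660), "garden"),),
    )


def _place_stream(rng: np.random.Generator, n: int, max_dur: int,
                  lo: int, hi: int) -> list[Interval]:
    placed: list[Interval] = []
    for _ in range(n):
        for _ in range(100):
            dur = int(rng.integers(1, max_dur + 1))
            start = int(rng.integers(lo, hi - dur + 1))
            cand = Interval(start, start + dur)
            if all(cand.end <= o.start or cand.start >= o.end for o in placed):
                placed.append(cand)
                break
    return sorted(placed)


def random_alignment_day(rng: np.random.Generator, n_sr_max: int = 3,
                         n_se_max: int = 3, max_dur: int = 20,
                         lo: int = 360, hi: int = 720) -> DayRecord:
    """Random small clustered day: both streams non-overlapping, short
    durations so exhaustive flow oracles stay cheap, placed in a window
    narrow enough that gaps fall both inside and outside typical bounding
    boxes."""
    srs = _place_stream(rng, int(rng.integers(0, n_sr_max + 1)), max_dur, lo, hi)
    ses = _place_stream(rng, int(rng.integers(0, n_se_max + 1)), max_dur, lo, hi)
    return DayRecord(
        participant_id="R", date="2017-07-03",
        self_reports=tuple(SelfReport(iv) for iv in srs),
        sensor_events=tuple(SensorEvent(iv, dose=1.0) for iv in ses),
    )
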