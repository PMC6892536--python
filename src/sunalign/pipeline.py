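"""End-to-end pipeline: preprocessing -> clustering -> alignment -> metrics.

Produces the cohort report tables: clustering stage summaries, per-stage
minute-level metrics (participant means), event-level counts with duration
statistics of false-positive reports and false-negative sensor events, and
the over/under-reporting day breakdown, plus a run manifest for
reproducibility.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import AlignedDay, align_day
from .clustering import (
    STAGE_NAMES,
    ClusterStageSummary,
    cluster_day,
    stage_percent_change,
    summarize_stage,
)
from .metrics import (
    DayLabel,
    EventMetrics,
    MinuteMetrics,
    classify_day,
    event_metrics,
    minute_metrics,
    overlap_minute_metrics,
    paired_pre_post_test,
)
from .preprocessing import DayRecord, DayStatus, preprocess
from .timeline import Config

ALIGN_STAGE = "Step 4: alignment (NFA)"


@dataclass
class RunManifest:
    config: dict
    input_paths: list[str]
    seed: Optional[int]
    timestamp: str
    software_version: str
    stage_record_counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class MetricsReport:
    """All cohort-level outputs of one pipeline run."""

    stage_summaries: list[ClusterStageSummary]
    stage_percent_change: dict[str, float]
    #: Per-stage participant-mean minute metrics (rows: pipeline stages).
    minute_table: pd.DataFrame
    #: Per-day post-alignment minute metrics.
    day_minutes: pd.DataFrame
    #: Whole-event counts summed over valid days.
    event_totals: EventMetrics
    #: Duration statistics of FP reports / FN sensor events (three scopes).
    fp_durations: pd.DataFrame
    fn_durations: pd.DataFrame
    #: One row per valid day with its over/under/equivalent label.
    day_classes: pd.DataFrame
    #: Over/under-reporting day summary.
    reporting_table: pd.DataFrame
    n_days_in: int = 0
    n_days_valid: int = 0
    #: Paired t on participant-mean Jaccard, pre vs post framework
    #: (None when too few participants or degenerate differences).
    jaccard_test: Optional[tuple[float, float]] = None


def _participant_means(per_day: pd.DataFrame, col: str) -> pd.Series:
    return per_day.groupby("participant_id")[col].mean()


def _duration_stats(durations: Sequence[int], scope: str) -> dict:
    arr = np.asarray(sorted(durations), dtype=float)
    return {
        "scope": scope,
        "n_events": len(arr),
        "mean_min": float(arr.mean()) if len(arr) else float("nan"),
        "sd_min": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
        "median_min": float(np.median(arr)) if len(arr) else float("nan"),
    }


def _event_duration_tables(
    aligned: Sequence[AlignedDay], cfg: Config
) -> tuple[pd.DataFrame, pd.DataFrame]:
    fp, fn = [], []
    for a in aligned:
        fp.extend(r.interval for i, r in enumerate(a.residuals.self_reports)
                  if a.sr_matched(i) == 0)
        fn.extend(e.interval for j, e in enumerate(a.residuals.sensor_events)
                  if a.se_matched(j) == 0)

    def table(intervals):
        peak = [iv for iv in intervals
                if cfg.peak_start <= iv.start < cfg.peak_end]
        over30 = [iv for iv in peak if iv.duration > 30]
        return pd.DataFrame([
            _duration_stats([iv.duration for iv in intervals], "6am-6pm"),
            _duration_stats([iv.duration for iv in peak], "10am-4pm"),
            _duration_stats([iv.duration for iv in over30],
                            "10am-4pm, >30 min"),
        ])

    return table(fp), table(fn)


def run_pipeline(
    days: Sequence[DayRecord],
    cfg: Config = Config(),
    out_dir: str | Path | None = None,
    input_paths: Sequence[str] = (),
    seed: Optional[int] = None,
) -> tuple[MetricsReport, RunManifest]:
    """Run the full framework over a cohort of day records.

    Non-valid days (no sensor data, true zeros) are excluded from metric
    aggregation.  When ``out_dir`` is given, the report tables, manifest and
    a per-day alignment dump are written there as CSV/JSON.
    """
    pre = preprocess(days, cfg)
    valid = [d for d in pre if d.status is DayStatus.VALID]

    per_day_stages = [cluster_day(d, cfg) for d in valid]
    summaries = [
        summarize_stage(name, [s[i] for s in per_day_stages])
        for i, name in enumerate(STAGE_NAMES)
    ]
    pct = stage_percent_change(summaries[0], summaries[-1]) if valid else {}

    aligned: list[AlignedDay] = []
    rows = []
    for day, stages in zip(valid, per_day_stages):
        a = align_day(replace(day, sensor_events=tuple(stages[-1])), cfg)
        aligned.append(a)
        stage_mms: list[MinuteMetrics] = [
            overlap_minute_metrics(day.self_reports,
                                   [e.interval for e in stage])
            for stage in stages
        ] + [minute_metrics(a)]
        for name, mm in zip(list(STAGE_NAMES) + [ALIGN_STAGE], stage_mms):
            rows.append({
                "participant_id": day.participant_id, "date": day.date,
                "stage": name, "tp": mm.tp_minutes, "fp": mm.fp_minutes,
                "fn": mm.fn_minutes, "jaccard": mm.jaccard,
            })
    per_day_all = pd.DataFrame(
        rows, columns=["participant_id", "date", "stage",
                       "tp", "fp", "fn", "jaccard"])

    stage_rows = []
    for name in list(STAGE_NAMES) + [ALIGN_STAGE]:
        sub = per_day_all[per_day_all.stage == name]
        row = {"stage": name}
        for col in ("tp", "fp", "fn", "jaccard"):
            means = _participant_means(sub.dropna(subset=[col]), col)
            row[f"{col}_mean"] = means.mean() if len(means) else float("nan")
            row[f"{col}_sd"] = means.std(ddof=1) if len(means) > 1 else float("nan")
        stage_rows.append(row)
    minute_table = pd.DataFrame(stage_rows)

    ev_totals = EventMetrics(*[
        sum(getattr(event_metrics(a, cfg), f) for a in aligned)
        for f in EventMetrics.__dataclass_fields__
    ]) if aligned else EventMetrics(0, 0, 0, 0, 0, 0, 0, 0, 0)
    fp_tab, fn_tab = _event_duration_tables(aligned, cfg)

    classes = [classify_day(a, cfg) for a in aligned]
    day_classes = pd.DataFrame([
        {"participant_id": a.day.participant_id, "date": a.day.date,
         "label": c.label.value, "discrepancy_min": c.discrepancy_minutes}
        for a, c in zip(aligned, classes)
    ], columns=["participant_id", "date", "label", "discrepancy_min"])

    rep_rows = []
    for label, sign in ((DayLabel.OVER_REPORTED, 1),
                        (DayLabel.UNDER_REPORTED, -1)):
        discs = [c.discrepancy_minutes * sign for c in classes
                 if c.label is label]
        rep_rows.append({
            "label": label.value,
            "n_days": len(discs),
            "pct_days": 100.0 * len(discs) / len(classes) if classes else 0.0,
            "total_discrepancy_min": sum(discs),
            "mean_discrepancy_min": (sum(discs) / len(discs)
                                     if discs else float("nan")),
            "sd_discrepancy_min": (float(np.std(discs, ddof=1))
                                   if len(discs) > 1 else float("nan")),
        })
    reporting_table = pd.DataFrame(rep_rows)

    jaccard_test = None
    pre_j = per_day_all[per_day_all.stage == STAGE_NAMES[0]].dropna(
        subset=["jaccard"])
    post_j = per_day_all[per_day_all.stage == ALIGN_STAGE].dropna(
        subset=["jaccard"])
    pre_means = _participant_means(pre_j, "jaccard")
    post_means = _participant_means(post_j, "jaccard")
    common = pre_means.index.intersection(post_means.index)
    if len(common) >= 2:
        try:
            jaccard_test = paired_pre_post_test(
                list(pre_means.loc[common]), list(post_means.loc[common]))
        except ValueError:
            jaccard_test = None

    post = per_day_all[per_day_all.stage == ALIGN_STAGE].copy()
    report = MetricsReport(
        stage_summaries=summaries,
        stage_percent_change=pct,
        minute_table=minute_table,
        day_minutes=post,
        event_totals=ev_totals,
        fp_durations=fp_tab,
        fn_durations=fn_tab,
        day_classes=day_classes,
        reporting_table=reporting_table,
        n_days_in=len(days),
        n_days_valid=len(valid),
        jaccard_test=jaccard_test,
    )

    manifest = RunManifest(
        config=asdict(cfg),
        input_paths=list(input_paths),
        seed=seed,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        software_version=__version__,
        stage_record_counts={
            "days_in": len(days),
            "days_valid": len(valid),
            **{s.stage_name: s.n_events for s in summaries},
        },
    )

    if out_dir is not None:
        _write_report(report, manifest, aligned, Path(out_dir))
    return report, manifest


def _write_report(
    report: MetricsReport, manifest: RunManifest,
    aligned: Sequence[AlignedDay], out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_df = pd.DataFrame([asdict(s) for s in report.stage_summaries])
    if report.stage_percent_change:
        stage_df = pd.concat([stage_df, pd.DataFrame([{
            "stage_name": "Percent change",
            **report.stage_percent_change}])], ignore_index=True)
    stage_df.to_csv(out_dir / "cluster_stages.csv", index=False)
    report.minute_table.to_csv(out_dir / "minute_metrics.csv", index=False)
    report.day_minutes.to_csv(out_dir / "day_minutes.csv", index=False)
    report.fp_durations.to_csv(out_dir / "fp_event_durations.csv", index=False)
    report.fn_durations.to_csv(out_dir / "fn_event_durations.csv", index=False)
    report.day_classes.to_csv(out_dir / "day_classes.csv", index=False)
    report.reporting_table.to_csv(out_dir / "reporting_days.csv", index=False)
    align_rows = [
        {"participant_id": a.day.participant_id, "date": a.day.date,
         "sr_id": i, "se_id": j, "matched_minutes": f}
        for a in aligned for (i, j), f in sorted(a.alignment.edge_flows.items())
    ]
    pd.DataFrame(align_rows, columns=[
        "participant_id", "date", "sr_id", "se_id", "matched_minutes",
    ]).to_csv(out_dir / "alignment.csv", index=False)
    (out_dir / "event_metrics.json").write_text(
        json.dumps(asdict(report.event_totals), indent=2) + "\n")
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
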