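# Methods

## Coordinates and conventions

All times are integer minutes since local midnight; intervals are half-open
`[start, end)`. Half-openness makes adjacent 6-minute sensor slots disjoint
and minute counting exact. A single local time zone is assumed; events never
cross midnight (the analysis window is 6am–6pm, 360–1080 min), and
multi-day events are rejected at ingest. Two distance primitives drive
everything: `overlap_minutes` (length of intersection) and `gap_minutes`
(length of the empty span between two intervals, 0 when they overlap or
touch). The same gap is used for fragment merging and for the alignment
bounding box; it is the only order-consistent choice that makes overlapping
pairs trivially assignable.

## Pre-processing

Events ending at or before 6am or starting at or after 6pm are removed.
Boundary-straddling events are **kept and clipped** to the window, so all
minute metrics are confined to the 720-minute analysis window; clipping a
whole straddler out instead would silently discount exposure that partly
falls inside the window. Straddling sensor readings are trimmed to whole
6-minute slots (counted from the reading's own start) so the quantization
invariant survives, with dose prorated by the retained fraction of slots —
a uniform-dose-within-reading approximation that only ever touches the two
edge readings of a day. Self-reports shorter than 15 minutes are dropped as
inconsistent with the reporting instructions. Non-wear is an **input flag**
(`DayRecord.worn`), never inferred: days with reports but no sensor data
are `no_sensor_data` only when flagged non-worn; days with neither stream
are `true_zero`. Both kinds are excluded from metric aggregation.

## Sensor clustering

Three steps, each per day:

1. *Isolated-reading removal.* A reading of exactly one quantum (6 min)
   whose gap to both neighbours exceeds τ_mds is treated as sensor noise
   and dropped. "Isolated" deliberately applies only to 6-minute readings:
   longer raw readings carry enough accumulated signal to survive this
   step, and step 3 still removes short clusters. The isolation threshold
   reuses τ_mds rather than introducing a second parameter.
2. *Fragment merging.* The transitive closure of "gap ≤ τ_mds = 6 min"
   partitions readings; each part becomes one event spanning earliest start
   to latest end, with dose summed (`math.fsum`) and fragment count kept.
   Merged events **bridge** the gaps they span, so total event duration can
   increase at this step while dose is conserved to floating point (the
   conservation tests assert 1e-12 relative agreement; bit-exact equality
   is not meaningful across different IEEE-754 summation orders).
3. *Short-event removal.* Events still shorter than the 15-minute reporting
   minimum are dropped — under 6-minute quantization exactly the ≤ 12-min
   events. Their dose leaves the running total.

The pipeline emits one cohort summary per stage (duration, event count,
days with any event, total dose) plus a percent-change row between input
and final stage.

## Network flow alignment

Pre-existing overlap between reports and events is locked in as true
positive before the network is built; the flow only re-assigns **residual**
minutes. This matches the intended semantics — alignment converts
over-reported (FP) minutes into matched (TP) minutes without disturbing
agreement that already exists.

The network: source → SRᵢ with capacity equal to the report's residual
minutes; SRᵢ → SEⱼ present iff `gap_minutes ≤ bounding_box` (inclusive at
60); SEⱼ → sink with capacity equal to the event's residual minutes.
Capacities are integers at 1-minute resolution, so max-flow integrality
guarantees whole-minute assignments; the solver is networkx's
`maximum_flow`. Flow splitting (one report feeding two events, or one event
fed by several reports) is permitted by construction. When multiple maximum
flows exist any is acceptable: every reported metric depends only on the
total flow, which is unique. After alignment,

    TP_after = overlap + flow,  FP_after = FP_before − flow,
    FN_after = FN_before − flow,

so `TP + FN = sensor minutes` and `TP + FP = report minutes` hold exactly
at every stage.

The greedy baseline processes reports in a caller-given order; each
exclusively claims its nearest (by gap) unclaimed event within the bounding
box, matching the smaller residual. Equidistant events resolve toward the
earlier-starting one. The flow optimum dominates every greedy order; the
test suite checks this exhaustively for up to 4 reports and checks the flow
itself against an independent dynamic-programming enumeration over integer
allocations on small instances.

## Metrics

Minute-level: TP/FP/FN as above; Jaccard `TP/(TP+FP+FN)`, reported as
missing (None) on empty days rather than 0. Event-level: a self-report is
a true positive iff its matched minutes (overlap + flow) are > 0; a sensor
event with zero matched minutes is a false negative. "Corresponding" is
thus defined through the alignment, since event metrics are computed after
it. Peak membership is by event start within [10am, 4pm); the long-exposure
sub-count requires strictly more than 30 minutes. Day classification uses
the signed discrepancy (report minutes − sensor minutes) against a
30-minute threshold, **inclusive** (≥ 30) by default with a strict mode
available (`Config.day_threshold_inclusive`), because "at least 30" and
"greater than 30" both appear as readings of the rule in the field.
Start-time histograms bin by integer start hour (6–17) and duration bins
[15, 30), [30, 60), [60, 120), [120, 180), [180, ∞) minutes.

The pre/post comparison is a paired two-sided t-test on **one value per
participant** (the mean over that participant's valid days), pre- vs
post-framework; day-level pairing would overweight heavy wearers. Zero
variance in the differences or fewer than two pairs is an error, not a
silent zero.

## Synthetic-data generator

The generator emulates a 10-day summer wear study of 37 adults. Latent
truth: per participant-day, an episode count from a negative binomial
(mean 2.5, dispersion 0.3; Poisson when dispersion is 0) and log-normal
durations (median 40 min, σ = 0.75), placed uniformly at random without
overlap in the 6am–6pm window. These defaults are anchored to published
cohort statistics of this study design: ≈ 2.5 exposure events per day with
mean event duration ≈ 48 min (≈ 2.2 h of daily exposure), ≈ 0.2 spurious
reports per day, and ≈ 48 J/m² of daily dose. Episodes are kept at least
one sensor quantum (6 min) apart: closer episodes would be
indistinguishable from a single episode after quantization, and their
quantized readings would collide.

Sensor channel: each episode is discretized into 6-minute slots from its
own start (so a noiseless episode yields one reading of duration
`quantize_duration_up(d)`); each slot independently drops out with
probability 0.1 (body shading), and surviving runs become readings. Dose
follows a deterministic diurnal cosine bell peaking at noon
(3.0 J/m² per slot), zero at the window edges — deterministic so that
dose-conservation tests are exact; stochastic dose (clouds) is out of
scope. Recall channel: episodes under 15 minutes are never reported;
others are omitted with probability 0.15 or reported with a Gaussian start
offset (sd 15 min, truncated to the day, duration preserved — the event is
remembered, its time misplaced); spurious reports arrive at 0.2/day.
Reports are kept mutually non-overlapping (the ingest contract) by
redrawing colliding offsets, falling back to perfect recall, and in the
rare remaining case dropping the report.

What the generator does *not* emulate: diurnal structure in episode start
times (real cohorts cluster at 9–11am), battery death and non-wear days,
duration-recall error, weather, clothing/sunscreen behavior. Passing tests
therefore demonstrate correctness of the pipeline's accounting and the
optimality of the alignment under the modelled error structure, not
calibration to any real cohort.

### A structural note on quantization

Because sensor events are quantized up to 6-minute multiples while reports
carry exact durations, even a perfectly recalled episode of d minutes
yields day Jaccard d/ceil₆(d) < 1, and episodes of 13–14 minutes are
sensed (quantized to 18 min, surviving clustering) but fall under the
reporting floor. Consequently, under offset-only recall noise the
alignment recovers essentially *all* recoverable over-reported minutes
(measured: ≥ 95% of FP minutes on 100% of seeded days) while per-day
Jaccard saturates around Σd/Σceil₆(d) ≈ 0.94–0.96 for realistic episode
durations rather than approaching 1. One acceptance-level check targets a
0.95 per-day Jaccard on 90% of days and remains unmet for this structural
reason; the equivalent recovery property is tested and green.

## Problem sizes and numerics

Property suites run on seeded cohorts of 200–500 synthetic days and on
exhaustive small alignment instances (≤ 3×3 with residuals ≤ 20 for the
enumeration oracle; ≤ 4 reports for greedy-order exhaustion) — sizes at
which the independent oracles are exact and the full suite completes in a
few seconds. The flow oracle is a memoized DP over integer allocations and
an LP-free, networkx-free route; the merge oracle is connected components
on an explicit gap graph. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
pipeline outputs (the manifest's timestamp aside).

## Known limitations

- The dosimeter is treated as ground truth for minute metrics; body
  shading means real over-reporting counts are upper bounds.
- Clipping boundary-straddling readings prorates dose uniformly within the
  reading.
- The alignment bounding box is a hard cut at 60 minutes; no cost gradient
  within the box (generalized-assignment extensions are deliberately out
  of scope).
- Day classification depends on totals only; a day with offsetting over-
  and under-reported episodes can classify as equivalent.
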