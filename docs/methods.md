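# Methods

## Scope and model

`lickometry` analyzes drinking behavior recorded by capacitive home-cage
lickometers in two-bottle-choice experiments.  The primitive observation is a
*lick*: one tongue-contact interval on a sipper, with an onset time and a
contact duration.  The package covers the full path from raw lick events to
publication-level summaries: bout segmentation, minute binning as a recording
device would perform it, artifact cleaning, windowed aggregation with
microstructure metrics, preference and intake analysis, and a calibrated
generative simulator that makes every stage testable without hardware or
animals.

### Bout segmentation

A drinking bout opens when three licks occur within less than one second
(onset-to-onset span of the triplet strictly `< 1000 ms`) and closes once no
lick follows within three seconds of the last lick's offset (gap strictly
`> 3000 ms`).  The closing 3-s silence is deadtime and is excluded from the
reported bout duration, so

    duration = last lick offset − first lick onset
             = Σ contact times + Σ within-bout gaps.

Tie-breaks are literal: a triplet spanning exactly 1.000 s does not open a
bout; a gap of exactly 3.000 s does not close one.  Licks preceding the
qualifying triplet are never retro-claimed into the bout, and a bout still
open at stream end is finalized at its last lick's offset.  Both thresholds
and the triplet size are parameters of `detect_bouts`.

`brute_force_bouts` re-derives the segmentation by exhaustively scanning
every candidate start index against the raw definitions.  It shares no code
with the single-pass detector and is the oracle in the property tests
(equality on thousands of randomized streams concentrated around the 1-s and
3-s boundaries).

### Minute binning

Counters mirror what an online recorder can know: each lick is credited to
the bin containing its onset; a whole bout's counters are credited to the
bin containing its last lick's offset, because the device can only book a
bout once it has closed.  The attribution bin is a documented choice — a
boundary-spanning bout could equally be booked at its onset bin; the closing
bin was chosen because it requires no look-back buffer in firmware.
Session-level conservation (Σ bout licks ≤ Σ licks, etc.) holds by
construction and is asserted in tests.

### Cleaning

Capacitive touch sensors occasionally fail to register release until the
next touch, inflating contact time without adding licks.  A minute bin is
treated as artifact-contaminated when it has contact time but no licks, or
an average contact time above 300 ms per lick (about six times a normal
lick).  Cleaning zeroes only the lick-duration counter of flagged bins; lick
counts and bout counters are untouched, and the operation is idempotent.

### Aggregation and metrics

Minute records are summed into half-open windows: clock-hour windows, 24-h
windows anchored to the clock hour of the first record, or 12-h light/dark
phase windows from the configured schedule (dark may wrap midnight).  Per
window and channel, four derived metrics are computed from the sums, each
undefined when its denominator is zero:

- average bout duration (s) = bout_duration / bout_count
- average bout size (licks) = bout_licks / bout_count
- lick frequency (Hz) = bout_licks / bout_duration   (ratio of sums)
- estimated interlick interval (ms) = (bout_duration − bout_lick_duration) / bout_licks

The interlick-interval estimator satisfies the exact identity
`bout_duration = bout_lick_duration + bout_licks · est_ili`; for a bout of
`N` licks with constant gap `g` it equals `(N−1)·g/N`.  Distribution
summaries (n, mean, SEM, median, IQR) are built from per-1-h-bin values;
interlick-interval values above 300 ms are excluded at summary time, flagging
bins whose duration counters were dominated by artifacts.  Exclusion at the
bin level (not per bout) is the default because the cleaning rule operates on
binned counters; quantiles use linear interpolation between closest ranks
(numpy's default), which matters for small n.

### Preference and intake

Preference for the experimental bottle is the percent share of a chosen
metric (licks by default; contact time, bout count, or bout duration as
alternatives) over the two-bottle total per window, undefined when the total
is zero.  Traces are smoothed with a length-6 moving average spanning three
preceding windows, the current one, and two following, shrinking at the
edges and skipping undefined windows; constant series are fixed points and
interior windows of a periodic series preserve the mean exactly.

Licks convert to volume through the linear calibration `licks =
736.4·ml − 1172` (slope default), i.e. ≈1.36 µl per lick.  The per-window
default inverts the slope only: the negative intercept maps zero licks to
+1.59 ml, which is meaningless for short windows.  The full inverse is
available for whole-period totals.  Bottle-weight validation regresses lick
totals on weight change (1 g = 1 ml) with ordinary least squares
(scipy.stats.linregress), reporting R², the F statistic on the slope
(F = t², df (1, n−2)), and a t-based 95% CI.

## The simulator

The generator is a marked point process chosen as the simplest mechanism
with interpretable knobs that reproduces the observed per-1-h-bin statistics:

1. **Bout initiations** per bottle: piecewise-homogeneous Poisson process,
   rate 1.6 bouts/h in the light phase and 3× that in the dark phase
   (12:12 schedule, lights off 19:00).  A lognormal between-cage factor with
   10% CV adds mild animal-level variation.
2. **Bout composition**: lick count N ~ round(Lognormal(µ=3.346, σ=0.6))
   (mean ≈ 34, right-skewed); contact times ~ Gamma(shape 10, mean 51 ms);
   within-bout gaps ~ Gamma(shape 8) around a per-bout mean gap drawn
   lognormally with mean 106 ms and CV 0.15.  The bout-level gap term models
   bout-to-bout licking-rhythm variability; without it, per-bin averaging
   symmetrizes the gamma gaps and the per-bin interlick-interval
   distribution loses the right skew seen in real data.
3. **Volumes**: each lick removes Gamma-distributed volume with mean
   1.36 µl (the inverse of the 736.4 licks/ml calibration) and 10% CV,
   giving ground-truth bottle weights (1 g/ml).
4. **Preference dynamics**: an optional per-day multiplier scales the
   experimental bottle's bout rate, emulating dose–response schedules.

With these defaults a cage drinks ≈ 48·1.6·34·2 ≈ 5200 licks ≈ 7 ml/day
across its two bottles.  Times are integer milliseconds throughout, so
device logs round-trip exactly and conservation laws hold without float
tolerance.

**Guard bands** keep the generated truth identifiable under the detection
rules: within-bout gaps above 2.5 s are resampled, the opening triplet is
resampled to span under 0.95 s, bouts have at least three licks, consecutive
bouts are spaced more than 3.5 s apart (a colliding Poisson start is pushed
forward), and a bout crossing the session horizon is truncated (dropped if
fewer than three licks remain).  Under guards, `detect_bouts` recovers the
true bout partition exactly — a property test, not a tolerance check.
Guards can be disabled to stress-test detection; the generator then only
prevents physical overlap of contact intervals.

**Artifact injection** operates on a finished log: stuck-sensor events add
`max(30 s, 320 ms × licks)` of contact time to randomly chosen bins (half of
them lick-free), which provably crosses the 300 ms/lick cleaning threshold,
so the cleaning stage can be scored exactly against the emitted manifest;
pause events delete a window of records and write PAUSE/RESUME markers;
timeout events write TIMEOUT markers.  Defaults are zero so the baseline
configuration is clean.

### What the simulator does and does not emulate

It reproduces circadian rate modulation, right-skewed bout-size/duration
distributions, realistic microstructure means, lick-to-volume coupling, and
the named sensor artifacts.  It does **not** model meal/bout clustering
beyond Poisson, ultradian rhythms, side biases, bottle-swap transients,
solution-dependent palatability effects on microstructure (these can only be
imposed via parameter schedules), or sensor-sensitivity drift.  Passing
pipeline tests on simulated data therefore demonstrates correctness of the
computations under the stated generative assumptions, not validity of those
assumptions for any particular dataset.

## Device-log dialect

No canonical file layout is published for this class of Arduino loggers, so
the package defines its own: a long-format CSV (one row per cage, side, and
minute) with a `#settings` header, a fixed column set, and marker rows
(START/PAUSE/RESUME/TIMEOUT/SD_FAIL/SIDE_SWAP/SOLUTION_CHANGE) interleaved
by timestamp — markers before data rows at the same minute.  Long format
scales to 36 channels and keeps marker lines greppable; timestamps are ISO
8601 at minute precision; bins elapsed during a pause are absent rather than
zero-filled.  Writing is canonical and byte-stable; reading enforces
monotone timestamps and non-negative counters, and `validate_log` reports
coded findings (missing bins outside pause windows, duplicate bins,
undersized bouts) without raising.  Alternative dialects can be layered on
by converting to `MinuteRecord` sequences.

## Numerical choices and degenerate inputs

- Derived metrics return `None` (NaN in exported frames) rather than 0 when
  undefined; preference windows with zero two-bottle totals stay undefined
  through smoothing.
- SEM of a single value is 0 by convention; empty summaries return an
  `n=0` sentinel with NaN statistics.
- The detector's totals are accumulated left-to-right so the detector and
  the brute-force oracle agree bitwise on float inputs.
- `fit_simple_regression` rejects n < 3 and zero-variance x.
- Simulator configs whose peak bout rate could not be spaced by the guard
  band (expected occupancy above 50%) are rejected up front.

## Problem sizes

The calibration checks and the acceptance recomputation run the full study
design — 16 cages × 2 bottles × 7 days, ≈ 590 000 lick events and 5 376
channel-hours — in well under a minute on one core; unit and property tests
use 1–2 cage × 1-day sessions and randomized streams of ≤ 200 licks.
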