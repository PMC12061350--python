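# Methods

## Problem and scope

`ambient_phenotype` analyzes behavior change in single-resident smart homes
during adverse external events (a pandemic lockdown, wildfire-smoke
episodes).  Ambient sensors — ceiling passive-infrared motion detectors,
door contacts on external doors, and background light/temperature units —
produce a timestamped event stream per home.  The package turns that stream
into five per-day digital behavior markers, quantifies an event's impact on
each marker with interrupted time-series (ITS) segmented regression,
clusters participants by their event response, and measures day-level
event/nonevent separability with a random forest.  A synthetic resident
simulator generates event streams and marker series with known structure so
every stage can be validated against ground truth.

## Marker definitions and detection rules

All rules operate on motion and door readings only; light and temperature
readings are periodic background and are ignored by the state machines
(counting them would mask the silences the rules depend on).

**Sleep (21:00–07:00 window).** A gap between consecutive motion readings is
sleep when the gap is at least 5 minutes and the reading *opening* the gap
came from a bedroom area.  Once asleep, a run of 3 or more contiguous
non-bedroom readings flips the state to awake; an awake episode bracketed by
sleep in the same night is recorded as a sleep interruption.  Detected sleep
segments run from the opener of the first qualifying gap to the first
reading of the awake-flip run (or to the last reading / the window edge).
Consequences of this construction:

* *sleep duration* = last-sleep minus first-sleep instant (span of the
  night, interruptions included), capped by the 10-hour window;
* *sleep efficiency* = summed segment time / span; undefined (missing) when
  no sleep was detected — the day is retained;
* *restlessness* (raw) = number of motion readings strictly interior to the
  detected segments.  Openers and closers are excluded, so a silent night
  scores 0.  Readings too few to flip the state (1–2 non-bedroom readings)
  count as restlessness.

A final reading-free gap from a bedroom reading to the 07:00 window edge
counts as sleep; without it a resident whose last stir precedes a silent
morning would lose the entire night.

**Out-of-home.** Scanning consecutive motion+door readings, an episode
starts when (i) the next reading is more than 20 minutes away, (ii) the
resident is awake at the gap start, and (iii) the reading before the silence
is an external-door event or motion in a door area.  Because a reading-free
gap implies an even longer motion-free gap, the published motion-gap
condition is implied.  The episode ends at the first reading of the next run
of 3 or more interior (motion) readings; a day ending mid-episode is clipped
at midnight and flagged open-ended.  *time out* = summed episode time.

**Activity level** (raw) = motion readings while home and awake, divided by
hours home and awake (24 h minus sleep overlap minus time out).  Counting
sleep hours in the denominator would conflate nighttime restlessness with
daytime activity, so they are excluded.

**Normalization.** Sensor count and density differ between homes, so the two
count-based markers (restlessness, activity) are z-scored per person with a
standard scaler (population SD) over *all* of that person's valid days, both
study periods pooled — per-period scaling would erase the very effect the
ITS measures.  Zero variance normalizes to 0 with a warning.

**Day validity.** Days with time out above half the day (strictly more than
43,200 s) and days where no sensor reported at all are flagged and excluded
from all downstream statistics; every removal is logged with its reason.

## Study windows

*Lockdown*: event days are the fixed lockdown range (2020-03-17 to
2020-05-21, 66 days) intersected with the monitored dates; baseline days are
the season-matched same month/day span one year earlier.  *Smoke*: event
days are maximal runs of ≥ 2 consecutive days with AQI > 100; baseline days
are equally many days with AQI ≤ 50 from the same calendar month, chosen
nearest to the run by date (ties broken toward earlier dates), without reuse
across runs.  Day indices t are positions in the ordered baseline-then-event
date list built *before* validity filtering; for contiguous ranges this is
the calendar offset, and filtered days keep their index, so trends remain
per calendar day.  The interruption index t0 is the first event day.

## Interrupted time-series model

For marker X_t with event indicator D_t,

    X_t = b0 + b1*t + b2*D_t + b3*(t − t0)*D_t + γ'z + ε_t

where b0 is the initial level (reported at the first observed day), b1 the
pre-event trend per day, b2 the immediate impact on the first event day, b3
the long-term trend per event day, and z the participant covariates (age,
gender, education), mean-centered so the intercept keeps its units.  The
default fit pools all participant-days in one OLS with participant-clustered
robust standard errors and t-based inference; the joint F test covers
{b1, b2, b3}.  Covariates that are constant within the fitted subgroup
(e.g. gender in a gender subgroup) are dropped with a warning.  A
per-participant mode fits each home separately and summarizes across homes
(mean coefficients, one-sample t-tests, Hotelling T² F for the joint null);
neither mode claims to reproduce any particular published degrees of
freedom, which are not derivable from day counts.  The counterfactual is the
pre-event line b0 + b1*t projected past t0 for the average participant;
algebraically counterfactual(t) − fitted(t) = −(b2 + b3 (t − t0)).

Significance statements use α = .05, two-sided, with no multiple-testing
correction.  Autocorrelated-error ITS (ARIMA errors, seasonality) is out of
scope.

**Reporting conventions.** Percent change is 100·|b2|/|b0| with the
direction carried separately as the sign of b2 — normalized markers can have
negative baselines, which makes signed percentages ill-defined, so only the
magnitude convention reproduces the published worked examples.  Seconds
convert to hours/minutes rounded to two decimals (one decimal for headline
hour differences).

## Phenotypes and separability

Per participant, the delta vector is the event-period mean minus the
baseline-period mean of each marker over valid days; participants missing a
period are excluded with a warning.  K-means (k = 3 default, 10 restarts,
best inertia, fixed seed) runs on per-marker z-scored deltas — the
seconds-scale markers would otherwise dominate the Euclidean distance —
while per-cluster statistics (mean delta, one-sample two-sided t-test
against zero) are reported on raw deltas.

The classification unit is the participant-day with the five markers as
features.  Tasks: 4-class (lockdown day / lockdown baseline / smoke day /
smoke baseline), pooled event-vs-nonevent, and the two per-event binaries.
Classes are balanced by seeded subsampling to the minority size, so chance
is 1/k; a 100-tree random forest under stratified 5-fold cross-validation
yields pooled out-of-fold accuracy, an exact binomial test against chance,
and Gini impurity importances averaged over fold models and renormalized to
sum to one.  Folds shrink with a warning when a class has fewer days than
folds.  No hyperparameter tuning or model selection over k is performed.

## Synthetic data generator

`simulate_home` emits one home's event stream from a daily routine plus a
ground-truth log (true sleep interval, interruption time, restless count,
outings, activity count).  Distributional choices, made once for
plausibility and simplicity: event counts (restlessness, indoor activity)
are homogeneous Poisson within their windows; the daily outing count is
Poisson truncated at 4; times and durations are Gaussian clipped to their
windows.  Defaults describe a realistic older single resident: bedtime
~22:10 (SD 20 min), ~8 h in bed, 1 restless reading/h asleep, a 15%-per-night
bathroom interruption (~12 min), 1.5 outings/day of ~2 h, and 15 motion
readings/h while home and awake spread over non-bedroom areas.

The generator is deliberately *exactly invertible* by the detection rules
under its defaults, which is what makes oracle testing sharp: bedtimes and
wake times are clipped into the 21:00–07:00 detection window; restless
readings keep a 6-minute guard from sleep edges and interruptions; mornings
start with a 3-reading non-bedroom run; daytime events start after 07:00;
outings are bracketed by door events and a 3-reading interior return run,
with a 25-minute minimum duration (shorter outings would be undetectable
under the 20-minute rule).  An external event perturbs the four routine
drivers (sleep duration, restlessness rate, daily time out, activity rate)
by an immediate shift plus a per-day trend, clipped back into the routine
invariants with a warning.  Infeasible days are regenerated (fatal after 100
retries).

What the simulator does **not** emulate: multi-resident homes and visitors,
pets, couch sleeping and naps, sensor dropout and jitter, outings shorter
than ~25 minutes or crossing midnight, daytime bedroom use, and
behavior-driven light/temperature signals (those channels are uninformative
background).  Passing oracle tests therefore shows the state machines invert
the stated rules, not that the rules are robust to every artifact of real
homes.

`simulate_marker_series` bypasses the event layer and draws daily marker
values directly from the segmented linear model plus i.i.d. Gaussian noise,
all participants sharing the generating coefficients.  Efficiency values are
not range-clipped in this statistical layer (clipping would bias coefficient
recovery).  The two presets encode published ITS coefficient tables as
generating truth: the lockdown arm (13 participants, 66 + 66 days; e.g. time
out initial 21,500 s, immediate impact −13,700 s) and the smoke arm (28
participants, configurable window length, with a self-generated AQI series
containing one >100 run and matched ≤50 days).  Default daily noise SDs:
1,800 s (sleep duration), 3,600 s (time out), 0.5 (restlessness z), 0.05
(efficiency), 0.3 (activity z) — roughly the day-to-day variability a stable
routine produces.

## Numerical and testing choices

Problem sizes in the test suite are chosen to exercise every rule while
keeping the suite fast: parameter-recovery uses 50 replicates of the full
13 × 132-day lockdown arm, confidence-interval coverage 200 replicates,
oracle equivalence 20 homes × 30 days, and pipeline tests a 4-home, 8+8-day
arm.  Oracle tolerances are ±10 min for sleep, ±5 min for time out, and
exactness for restless counts; the simulator's construction keeps the actual
errors to seconds (door-bracket and morning-run offsets).  All randomness
flows through explicit integer seeds (`numpy.random.default_rng`); the same
seed reproduces byte-identical streams and reports.

Known limitations: the pooled OLS ignores serial correlation within homes
beyond what clustering absorbs; smoke baseline days being scattered makes
their day index a rank, not a calendar offset; percent change is undefined
at zero baseline and reported as missing; and a published percentage that
was computed from unrounded coefficients can differ from the
printed-coefficient recomputation in the last digit.
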