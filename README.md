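# ambient-phenotype

Digital behavior markers from ambient smart-home sensors, with interrupted
time-series event-impact analysis.

Older adults living alone increasingly weather adverse external events —
pandemic lockdowns, wildfire-smoke episodes — inside their homes.  Ambient
sensors (ceiling passive-infrared motion detectors, door contacts on
external doors) record daily routine unobtrusively, and changes in that
routine carry clinical signal.  This package is for researchers working
with such event streams: it extracts five per-day **digital behavior
markers** — sleep duration, sleep efficiency, sleep restlessness, time out
of home, activity level — from raw sensor events, and quantifies how an
external event changed them.

## The model

Each marker's daily series X_t is analyzed with interrupted time-series
segmented regression around the event start t₀:

    X_t = β₀ + β₁·t + β₂·D_t + β₃·(t − t₀)·D_t + γ′z + ε_t,   D_t = 1[t ≥ t₀]

β₀ is the pre-event baseline, β₁ the pre-event trend per day, β₂ the
immediate impact on the first event day, β₃ the long-term trend during the
event, and z are participant covariates (age, gender, education).  The
counterfactual — behavior had the event not occurred — is the pre-event
line β₀ + β₁·t projected past t₀.  Downstream, per-participant
event-vs-baseline marker deltas are clustered into phenotypes (k-means,
k = 3), and a 100-tree random forest under stratified 5-fold
cross-validation measures how separable event and baseline days are,
ranking markers by Gini importance.

A bundled simulator generates single-resident homes (night sleep with
restlessness and interruptions, daytime outings bracketed by door events,
indoor activity) together with ground-truth logs, plus marker series with
known segmented-trend structure; presets encode published coefficient
tables for a pandemic-lockdown arm and a wildfire-smoke arm.

## Worked example

`examples/fit_event_impact.py` simulates the lockdown arm (13 homes, 66
baseline + 66 lockdown days, 1-hour daily noise on time out) and fits the
segmented regression:

```
segmented regression on daily time out (seconds):
  initial level        21687   (generating: 21500)
  pre-event trend      -8.41   (generating: -6.00)
  immediate impact    -13913   (generating: -13700)
  long-term trend      32.51   (generating: 26.00)
  F = 2875.0 on df (3.0, 12.0), p = 2.1e-17

time out fell from 6.02 h/day to 2.16 h/day on the first lockdown day (3.9 h, a 64.15% decrease)
counterfactual gap on the last lockdown day: +3.28 h
```

The fitted coefficients recover the generating ones within noise: on the
first lockdown day the average resident's time out of home drops by ~3.9
hours, and the counterfactual gap shows where the pre-event trend would
have put them by the end.

Other examples, one per capability:

- `examples/simulate_and_extract.py` — simulate a home, run the extraction
  state machines, compare to ground truth (sleep/time-out agree to minutes,
  restless counts exactly);
- `examples/reporting_arithmetic.py` — percent-change and hour/minute
  reporting conventions applied to the preset coefficient tables;
- `examples/phenotype_clusters.py` — k-means phenotypes of smoke-arm
  deltas with per-cluster statistics;
- `examples/classify_event_days.py` — random-forest separability and Gini
  marker ranking.

A thin CLI mirrors the pipeline (`ambient-phenotype simulate / extract /
windows / analyze / phenotype / classify / run / plot`); see
`ambient-phenotype --help`.

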