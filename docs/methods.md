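# Methods

This note documents the models, rules and numerical choices in
`adlhome`, what the synthetic generator does and does not emulate, and
therefore what a green test does and does not establish.

## The problem and the pipeline

Instrumental ADLs (cooking, chores, medications, grooming, appliance
use, going out) decline early in dementia, and ambient smart-home
sensors can observe them objectively in a resident's own home. The
pipeline converts raw sensor events into an hourly behavioural feature
table, personalizes it against each resident's own routine stratified by
cognitive level, and classifies normal controls vs early-stage dementia
with a random forest.

## Sensor conversions (preprocess)

All bins are half-open `[start, start + width)`, labelled by start;
widths 10 min, 1 h, 1 day. An episode spanning a boundary contributes
duration to every bin it overlaps and count 1 to its start bin, so
daily counts equal summed hourly counts equal summed 10-min counts
(asserted as a property test).

| rule | default | why |
| --- | --- | --- |
| tilt tolerance | 10° from the resting pose `(0,0,1)` | a use is a deliberate re-orientation; small wobble is noise |
| tilt restore timeout | 600 s | unclosed uses truncate rather than run on |
| plug on-threshold | 5 W | standby draw exists; power is held between readings |
| plug debounce | 60 s | brief dips (compressor cycles) are one session |
| temp rise delta | 2 °C over a 600 s rolling window | a stove/shower excursion, not drift; episode ends within delta/2 of the frozen baseline |
| motion merge gap | 60 s | detections closer than this form one activity episode for duration accounting |
| gait floor | 0.6 km/h | both groups' published minimum prints 0.600, implying a floor filter; displacement below the floor still accrues to movement distance |
| zone minimum dwell | 5 s | lidar jitter at zone boundaries |

The temperature baseline is the median of out-of-episode readings in
the trailing window and freezes during an episode; a slow drift
therefore never triggers, only a rise faster than the window.

Counts increment on on-transitions (door opens, plug switch-ons, tilt
uses, detections), not on every state change — the day-unit example
table does not disambiguate, so this is a documented choice.

## ADL rules (adl)

- **Cooking**: kitchen-appliance events within a rolling 30-min window
  form a cluster; cooking iff ≥ 2 distinct appliance channels and an
  overlapping stove temperature rise (each rise is consumed by at most
  one cluster, so cooking count ≤ stove-rise count). A cluster with the
  microwave and no rise is *heating food*. The episode spans the
  earliest to latest contributing event; duration-over-30-min is a tag.
  Appliance-pair tags (refrigerator–sink, sink–rice-cooker,
  refrigerator–stove, stove–microwave) mark simultaneous use.
- **Windows** (wall-clock, no DST): meals 05–10 / 12–15 / 17–20;
  medications add bedtime 21–24; grooming nighttime 00–04; TV morning
  04–12 and night 00–04; mat daytime 12–16 and night 00–04. Point-like
  ADLs tag by start time; TV/mat sessions tag by overlap (a session
  03:00–05:00 carries both night and morning tags).
- **Outings**: an entrance-door toggle opens a candidate; it needs
  ≥ 600 s with zero interior motion, closes at the next toggle, and
  requires motion within 300 s of the return. Appliances whose
  on-interval covers the whole absence are "left on"; `lock_ok` means
  nothing left on and no lighting observed during the absence (lux is
  only reported with motion detections, so an empty absence reads as
  lights-off). TV starting within 30 min of return sets the
  TV-after-return flag.
- **Chores**: sink uses ≥ 30 s are washing dishes (monotone in the
  threshold); washer plug intervals are laundering. Hand-wash laundry is
  explicitly unmeasured.
- **Wandering** is emitted as per-bin metrics (zone visits and dwell,
  room↔living-room transitions, all-channel event count in 00:00–05:00)
  rather than episodes, because its feature set is defined as
  sub-features.

## Feature schema

195 columns on the reference roster. The roster packs 65 per-channel
sensors (8 door, 18 motion, 10 plug, 6 temperature-humidity,
23 vibration) across 6 zones of a 10 m × 8 m flat; the real study never
enumerates its 65 channels, so the roster is a documented stand-in sized
to reproduce the counts: 65 counts + 65 durations + 2 lidar = 132
IoT-side; 31 ADL features × {count, duration} + one count-only
medication total = 63 ADL-side. Which single feature is count-only is
likewise unstated in the source material; the medication total was
chosen because medication taking is defined purely by use counts.

## Personalization

Per person and feature, the normal range is
`[Q1 − k·IQR, Q3 + k·IQR]` with quartiles by linear interpolation over
an expanding window of strictly earlier bins (shifted by one bin), with
a 24-bin minimum history before any flag. k follows the MMSE bands
30 / 27–29 / 24–26 / ≤ 23 → 1.5 / 1.2 / 1.0 / 0.5; the interior split of
the 24–29 range is an even split, configurable, because only the
endpoints are pinned down. Smaller k flags a superset of anomalies
(nestedness is an acceptance property); zero-IQR features flag exactly
values ≠ Q1.

Both per-bin indicators and rolling per-day counts are computed; the
personalized dataset fed to the classifier is raw features + per-bin
indicators (`augment` mode; a `replace` mode exists). Day counts are a
near-deterministic function of the indicators, so they are kept out of
the default classifier input.

Note the personalization is *label-correlated by design*: k derives from
MMSE, which separates the groups. That is the point of the method — the
anomaly features encode deviation-from-own-routine at group-dependent
strictness — but it means the personalized-vs-raw comparison measures
the value of that construct, not of anomaly detection per se.

## Statistics

`spearman_r` implements the classical `1 − 6Σd²/(n(n²−1))` for tie-free
ranks and falls back to the product-moment correlation of average ranks
under ties (the formula assumes distinct ranks); constant input is
undefined (NaN + warning). The rank-sum test uses the exact null for
n ≤ 20 without ties, otherwise the normal approximation with continuity
correction (scipy's Mann–Whitney implementation; the reported statistic
is the rank-sum W). Group comparisons run Shapiro–Wilk per group first
and take the rank-sum branch whenever either group rejects at α = 0.05;
no multiple-testing correction by default (per-variable reporting), with
an optional Benjamini–Hochberg switch. Appliance correlations use daily
(1-day bin) counts.

## Classification

Random forest, 500 trees by default, √p features per split, unlimited
depth, fixed seed; stratified record-level 10-fold cross-validation
(person-hours of both groups pooled — the original design), pooled
metrics recomputed from summed confusion counts. A grouped
(leave-persons-out) mode exists as a leakage diagnostic and is a
labelled deviation: record-level pooling lets a person's own hours
appear in both train and test folds, which inflates absolute accuracy.
Positive class is dementia.

Shapley importance uses seeded permutation sampling (marginal
contributions along random feature orderings against background rows),
since no exact tree-path implementation is available in the target
environment; it converges to the exact values in expectation and is
deterministic given the seed.

## Synthetic cohort: the stated world

Defaults: 7 normal + 6 dementia personas, 14 days, hourly grid. MMSE is
drawn uniformly on 25–30 (mean 27.5) for controls and 12–23 (mean 17.5)
for the dementia group, matching the published group means; CDR is 0
for controls and 0.5 (1 in 6) or 1 otherwise.

Group contrasts are persona parameters, not label look-ups:

| parameter | normal | dementia | emulates |
| --- | --- | --- | --- |
| appliance coherence | 0.85 | 0.25 | loss of correlated kitchen-appliance use |
| night activity (events/h, 00–05) | 0.2 | 1.5 | late-night life patterns |
| medication adherence / jitter | 0.9 / 10 min | 0.6 / 40 min | irregular dosing |
| forget-appliance-on outings | 0.05 | 0.5 | no-lock exits |
| gait mean ± sd (km/h) | 1.023 ± 0.35 | 1.209 ± 0.45 | published group means (the dementia group's printed mean is the larger; kept as printed) |
| task duration scale | 1.0 | 1.5 | slower task completion |
| meal cooking probabilities | .8/.6/.9 | .55/.45/.65 | reduced cooking |

Speeds are lognormal (moment-matched), sampled per walk segment at 1 Hz
along straight lines between zone centroids. The dwelling is silent
00:00–05:00 except persona night activity, so a zero night rate is
exactly silent at night. Standard deviations, session probabilities and
background-noise rates are not published anywhere; they were chosen once
as qualitatively realistic for a single elderly resident (about 1–3 k
event rows/person-day, an order of magnitude below a real deployment's
raw record rate) and are not tuned against test outcomes.

**What the generator does not emulate**: sensor dropout and clock skew,
seasonal/weekday structure, visitors, multi-resident confounds, hardware
artifacts, or the months-long observation of a real deployment. A green
directional test therefore establishes that the pipeline recovers the
contrasts the generator encodes — not that those contrasts have clinical
effect sizes. Absolute cross-validated accuracies at desk scale
(≈ 0.65–0.75) are accordingly below the ≈ 0.85–0.91 reported on real
months-long data, and the tests assert only the personalized ≥ raw
direction, which is stable across seeds.

## Reproducibility and budgets

Everything is deterministic given a root seed: per-person and per-day
random streams spawn from one `SeedSequence`; pipeline stages derive
seeds by hashing `seed:stage` (< 2³¹). `run_all` writes CSV artifacts
plus a manifest keyed by a hash of the scientific config (output path
excluded); two runs with the same config are byte-identical.

Where wall-clock budgets matter (the acceptance battery and the
acceptance script run on one CPU), forests use 100 trees instead of the
500-tree library default and the determinism check uses a reduced
cohort; these are runtime scalings, documented at the call sites, and do
not change any rule or generator parameter.

## Known limitations

- The 65-channel roster reproduces the published feature *counts*, not
  the (unpublished) channel identities.
- Cooking duration is the episode span (earliest to latest contributing
  event); the source material states only that duration "combines" the
  sensor values.
- Record-level folds are kept as the primary design for fidelity; use
  the grouped mode to estimate person-level generalization.
- Lux is observed only at motion detections, so the lights-off half of
  the lock check is vacuous during a truly silent absence.
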