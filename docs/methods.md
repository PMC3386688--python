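# Methods

This note records the statistical model, the defaults and the design
choices behind `lifemon`, and what the synthetic benchmarks do and do not
demonstrate.

## Windowing and labeling

Days are calendar days in the log's local clock with the boundary at
midnight; timestamps are truncated to whole seconds. A day is tiled with
half-open windows `[t, t + T)`; `T` must divide 86,400 s so the tiling is
exact. The default `T = 60 s` balances discriminative power against label
granularity for object-sensor streams; 600 s is the standard coarse
comparison point and both are exercised by `lifemon evaluate`. A window's
feature for sensor *s* is 1 iff an activation interval of *s* (treated as
half-open) overlaps the window — the "raw" representation; a change-point
variant was considered and rejected as harder to reason about with no
observed benefit on binary object sensors.

Training labels come from annotations by majority overlap: the annotation
covering the largest fraction of the window wins, ties go to the earlier
annotation, and uncovered windows get the reserved label `idle`. `idle`
is a first-class prediction target, not an error state.

## Classifier

A C4.5-style tree on binary features: splits maximize gain ratio
(information gain over split information), each feature is used at most
once per path, and leaves predict the majority class with lexicographic
tie-breaks. Two deliberate deviations from a textbook C4.5:

* An impure node is split whenever *some* remaining feature separates its
  samples, even at zero immediate gain. Binary object signatures are
  often only jointly informative (two activities sharing a sensor are
  distinguished by a second one); pure gain-gating stops too early on
  such data. This guarantees zero training error on consistent data at
  `min_leaf = 1`. Tree size stays bounded by the number of distinct
  feature vectors.
* Duplicate (vector, label) rows are collapsed to weighted counts before
  growing. Entropies, majorities and `min_leaf` are computed on the
  weights, so the tree is mathematically identical to one grown on the
  raw rows but trains in time governed by the number of *distinct*
  windows (tens, not tens of thousands).

`min_leaf` defaults to 2 (children of a split must each receive two
training windows); training is fully deterministic — equal gain ratios
resolve to the lowest feature index, equal leaf counts to the
lexicographically smallest label. Optional pruning replaces a subtree by
a leaf when the leaf's pessimistic error (binomial upper confidence bound
at the 25% level) does not exceed the subtree's; pruned training accuracy
therefore never exceeds unpruned. Evaluation is leave-one-*day*-out:
per-day folds respect the strong within-day dependence of windows, and
the report carries per-fold counts, the confusion matrix and the window
size. `scikit-learn`'s entropy tree serves as an independent cross-check
in the test suite, never as the implementation.

With only two days of data and `min_leaf = 2`, activities occupying a
single 600 s window per day cannot be isolated in a one-day training
fold; the two-window-size evaluation example therefore uses a three-day
fixture.

## Frequency regularity

Episodes are maximal runs of equal non-idle window labels; a single
intervening idle window does not split an episode (tolerance 1 window),
bridging one-window recognition dropouts, while two or more idle windows
— or any window of another activity — do split. The daily activity
frequency (DAF) of a count DIA is the day's episode count. Two DIAs are
not episode counts: *movement* is the number of transitions between
distinct sensor locations in the day's event sequence (binary object
sensors carry no positioning, so room-to-room transitions are the only
location-bearing signal), and scalar DIAs (weight, lighting) take the
daily measurement directly.

Profiles are fitted per DIA over the training days: RAF is the arithmetic
mean DAF and the dispersion the sample standard deviation (`ddof = 1`).
During training the DAFs come from the ground-truth annotations (and the
raw events, for movement): they are the exact record of the training
period, and using them keeps classifier error out of the baseline the
monitoring phase is compared against. A single training day yields
`sd = 0` with a warning.

Grading maps the z-score to five integer bands with boundaries assigned
to the more-regular band: the regular band is the closed interval
`−1 ≤ z ≤ 1`; the outer cutoffs sit symmetrically at `|z| = 2`, a
convention of this package. With `sd = 0`, any deviation from the RAF is
infinitely many standard deviations by the model, so the grade is 0 on an
exact match and ±2 otherwise. Grading is monotone in the DAF value and
antisymmetric about the RAF.

`format_daf_delta` renders monitoring tables as `2(▲ 1)` — the day's
value with its change against the *rounded* RAF (Python's banker's
rounding; the display is cosmetic and does not feed any computation).

## Risk scoring

The normalized pattern distance between two grade vectors of length *n*
is the Euclidean distance divided by `sqrt((GAF_MAX − GAF_MIN)² · n)` =
`sqrt(16 n)`, the distance between the all-(+2) and all-(−2) vectors; it
is a metric scaled to [0, 1]. The risk score is `1 − distance` and an
alert fires when risk strictly exceeds the disease threshold (default
0.9 when a registration omits it). Note that under this convention a
fully *regular* day still scores 0.5 against the diabetes pattern — the
score measures proximity to the disease pattern, not evidence of
abnormality per se — which is why reports carry the raw distance ratio
alongside the risk and why thresholds should be set high. Disease
patterns may be written as band names (`"very high"` …) or integers; the
bundled diabetes registration is `(2, 2, 2, 2, −2)` over (eating,
sleeping, movement, toileting, weight). The bundled depression file is a
synthetic stand-in: its DIA list follows the usual depressive signs but
its grade vector is an illustration chosen here, not a clinically
validated pattern.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets: a
single resident, object-embedded binary sensors, per-activity daily
episode counts. Counts are drawn as `round(Normal(λ, σ))` truncated at 0
— matching the normality assumption the regularity model makes about
DAFs — with Poisson available as an option. Durations are normal,
clipped to `mean ± 3 sd` (and ≥ 30 s) so a tail draw cannot overflow the
day; a day whose episodes genuinely cannot fit raises an error rather
than silently overlapping. Placement is uniform over non-overlapping
arrangements (random episode order, Dirichlet gaps over the free time).
Each episode activates its mapped sensors within its own interval, so
events and annotations are mutually consistent by construction. Optional
noise — per-episode sensor misses and spurious activations — defaults to
0.

The default home has nine sensors in four rooms and six activities with
realistic rates: sleep occupancy 1.5/day × 4 h (binary bed sensors report
fragmented occupancy episodes, not one continuous night), three meals,
five toilet visits, one shower, one outing, two medication intakes; daily
weight 189.8 ± 1 lb and lighting 300 ± 30 lux. The diabetes-shaped drift
triples toileting, doubles eating, raises sleep occupancy ×1.5 and drops
weight by 3 sd — deviations chosen to be unambiguous (z ≫ 2) against
25-day training profiles. Episodes never cross midnight; weekly
seasonality, trends, visitor traffic and multi-resident confusion are not
modeled. Passing tests on this generator therefore demonstrate the
pipeline's statistical machinery and end-to-end wiring, not recognition
accuracy on real homes, where label noise, sensor sharing between
activities and non-stationary routines dominate.

The separable fixture is the degenerate noise-free case: one unique
sensor set per activity (including a medication episode firing Cabinet +
Water glass + Purifier), an identical daily schedule aligned to a
10-minute grid, so recognition is exact at both 60 s and 600 s windows.

## Pipeline and problem sizes

`train` fits the tree on the annotated training range and persists it as
a JSON tree document beside a `profiles.csv`; `monitor` classifies each
monitoring day, builds the timeline, grades every DIA, assembles one DAP
and one risk report per disease per day, and writes CSV/JSON-lines
mirrors of everything; both are deterministic given config and seed. The
end-to-end drift study used in the tests trains on 25 simulated days and
monitors 10 (5 clean, 5 drifted) at 60 s windows — about 50,000 windows
per run — and repeats over 20 seeds, a size chosen to give stable means
while keeping the whole suite fast on one CPU.

## Known limitations

* Risk is pattern proximity; it does not incorporate the base rate of the
  disease or the joint distribution of GAFs, and a regular day scores a
  nonzero risk against any non-regular pattern.
* The grading bands' outer cutoffs (|z| = 2) and the sd = 0 rule are
  conventions; different choices shift individual GAFs by one band near
  the boundaries.
* Movement-as-transitions undercounts movement that stays within one
  room and is sensitive to sensor placement density.
* Single resident only; annotations are assumed non-overlapping.
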