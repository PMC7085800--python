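# Methods

## Problem setting

Ambient smart-home sensing produces a stream of timestamped binary
sensor events (motion sensors switching ON/OFF, optionally temperature
readings). In annotated logs, some events additionally carry an activity
name and a `begin`/`end` marker. The task is to recognise which activity
of daily living (ADL) an unlabelled instance belongs to, in a home with
**two residents**, where one resident's activity window is polluted by
events the other resident triggers.

An activity instance is reduced to `a = {bt, et, sq}`: the hour of day
of its first event (`bt`), the hour of its last event (`et`), and the
ordered sequence of sensor IDs fired between them (`sq`). When two
activities overlap in time, every event in the intersection belongs to
both sequences — this is what makes the two-resident problem hard, and
what the de-noising stage targets.

## Pipeline

### 1. Sensor-importance de-noising

For every start sensor `s0`, the SIA (sensor-importance table) records

    importance[s0][s] = #{sequences starting with s0 that contain s}
                        / #{sequences starting with s0}

Sensors genuinely belonging to an activity recur in almost every
instance of its class (importance near 1); a co-resident's sensors
appear only on the days the schedules happen to collide (importance near
the collision rate). De-noising makes a single in-order pass over `sq`
and drops an element if (i) it equals the previously kept element
(consecutive-duplicate collapse), or (ii) its importance under the
sequence's original start sensor is **not strictly greater than** the
threshold `w`. The start sensor always survives (its importance is 1 by
construction). The pass is idempotent, and is equivalent to applying the
importance filter first and collapsing duplicates second — a property
test asserts the equivalence rather than assuming it.

**Threshold `w` (default 0.25, dimensionless).** The smallest importance
a sensor can have in a two-instance class is 0.5, so 0.25 keeps every
worked-example sensor while removing interference whose collision rate
stays below one day in four. It is exposed via `DenoiseConfig`, the CLI
flag `--w-threshold`, and YAML config.

An alternative `dedup="global"` mode keeps only the first occurrence of
each sensor; the default is consecutive-only collapse, which preserves
revisit structure (e.g. a return path through a hallway sensor).

De-noising is fundamental­ly a *sporadic*-noise filter: interference that
is systematic (the co-resident does the same thing at the same time
every day) is indistinguishable from the activity's own signature at
this level of description and is not removed.

### 2. Time clustering and the elbow

Instances are clustered by k-means on the unscaled `(bt, et)` plane
(both axes are hours on the same 0–23 range, so no standardisation;
hour differences are linear, not circular). The fit uses k-means++
initialisation, 10 restarts, Lloyd iterations, and a fixed seed — fully
deterministic. Quality is the within-cluster sum of squared errors

    SSE = Σ_i Σ_{p ∈ C_i} ‖p − m_i‖²

The cluster count is chosen at the **elbow** of the SSE-vs-k curve,
scanned for k = 1 … number of activity classes. "Highest curvature" is
computed literally: both axes are min–max-normalised and the discrete
curvature |y″| / (1 + y′²)^{3/2} (second difference over central first
difference) is maximised over interior k. The normalisation is load-
bearing: on the raw scale the steep initial drop of SSE makes either the
second difference alone (always picks k = 2) or the unnormalised
curvature (picks a k in the flat tail, where y′ ≈ 0) select the wrong k.
On planted three-cluster data the normalised curvature recovers k = 3 in
100 of 100 seeds. A kneedle-style alternative (maximum vertical distance
below the chord of the normalised curve) is available via
`select_k(..., method="kneedle")`.

### 3. Similarity voting

A test instance `t` is assigned to the nearest centroid and compared
against the training instances of that cluster with

    ratio = w1·(24 − |a.bt − t.bt|)/24 + w1·(24 − |a.et − t.et|)/24
          + w2·LevRatio(a.sq, t.sq)

subject to `2·w1 + w2 = 1` (so identical instances score exactly 1) and
`2·w1 ≤ w2` (the sensor sequence dominates the time terms — the cluster
step has already handled coarse time structure). Defaults: `w1 = 0.15`,
`w2 = 0.7`, vote count `n = 5`; `n` should stay below the number of
activity classes.

`LevRatio` is the normalised Levenshtein similarity over whole sensor-ID
tokens: `(|sq1| + |sq2| − ldist) / (|sq1| + |sq2|)` where `ldist` costs
insertions/deletions 1 and substitutions 2. The substitution-cost-2
convention is the only one under which the ratio is bounded in [0, 1]
(it then equals the fraction of tokens matched by a longest common
subsequence, counted over both sequences); a unit-substitution variant
is available for sensitivity analysis. Comparing tokens rather than
concatenated characters matters: as characters, "M004" and "M005" would
spuriously share three quarters of their symbols.

The majority label among the top-n neighbours wins; vote ties are broken
by the greater summed similarity, then lexicographically — predictions
are fully deterministic.

### 4. Evaluation

Stratified five-fold cross-validation with a fixed seed. Per fold the
SIA is rebuilt **from the training fold only** (no label leakage), both
folds are de-noised with it, k-means is fitted on the training fold
(k by elbow unless fixed), and every test instance is recognised.

Metrics are one-vs-rest per class from the pooled confusion matrix
(rows = predicted, columns = actual):

    Accuracy = (TP+TN)/total   Precision = TP/(TP+FP)
    Recall   = TP/(TP+FN)      F = 2·TP/(2·TP+FP+FN)

Macro values are unweighted class means; the headline numbers are the
means of the per-fold macro metrics, with per-fold reports and the
pooled matrix attached. Micro accuracy (trace/total) is reported
alongside, since published headline "accuracy" figures are often micro.
Zero-denominator ratios are reported as 0 and flagged `degenerate`
rather than propagating NaN into the macro averages. A class with a
single instance stays in training only, with a warning.

## Synthetic two-resident generator

Real annotated two-resident logs are large external downloads, so the
package ships a generator with the statistical structure the method
assumes, plus exact ground truth.

Each **activity template** has a start-hour distribution (truncated
normal on [0, 24)), a duration distribution (normal in minutes,
truncated below at 1), an ordered sensor path, and per-step repeat/skip
probabilities. Per day and resident each template is instantiated once:
the first and last events carry the `begin`/`end` annotation, interior
events get sorted uniform timestamps inside the span. Cross-resident
**interference** is injected as Poisson(`interference_rate`) extra
events per instance, strictly inside the span, carrying a sensor of the
other resident's nearest-in-time template that is foreign to the host's
own path, with no annotation — exactly how a co-resident pollutes an
activity window. Injected sensors are recorded per instance in the
ground truth. Everything is deterministic given the scenario seed.

**Default scenario** (the package's standard test bed): 2 residents ×
4 activities = 8 classes, 60 days (480 instances), interference rate
0.3, repeat probability 0.15, skip probability 0.05. The eight
schedules sit in three time bands (morning ≈ 5.8–6.8 h, noon ≈ 12–13.7 h,
evening ≈ 18.7–21.5 h) — three planted (bt, et) clusters. Within a band
the two residents are staggered so span overlap happens on a few percent
of days (occasional, never systematic), and each template visits four
distinct sensors (32 sensors total, comparable to a real multi-sensor
apartment) so injected interference spreads thinly across sensors. Both
choices reflect the regime the de-noising stage is built for; under
them, ~98% of instances with injected interference are fully cleaned at
`w = 0.25`.

A `noise_free_scenario` variant (no interference, no repeats/skips,
tightly separated windows) is the degenerate limit in which every
sequence equals its template path and recognition is exact — useful as
an end-to-end correctness check rather than a difficulty benchmark.

**What the generator does not emulate:** sensor-adjacency/floor-plan
geometry (interference sensors are chosen by schedule proximity, not
spatial proximity), OFF-event semantics (all generated statuses are ON),
activities spanning midnight (spans are clipped at 23:59:59.999999),
shared sensors between different activities' signatures, and label
noise. Passing tests therefore demonstrate the pipeline's behaviour
under regular, vocabulary-separable schedules — they do not certify
performance on real homes where distinct activities share rooms and
sensors.

## Numerical and procedural choices

- **Segmentation**: an event between a matched `begin`…`end` pair joins
  *every* activity open at that moment, begin and end events included.
  If the same activity name is open twice, an `end` closes the earliest
  open instance (FIFO). Unmatched ends and still-open activities are
  skipped with warnings. `bt`/`et` are taken literally from the hour
  fields (no midnight wrap-around treatment).
- **Parsing**: any run of whitespace delimits; temperature (`T…`) events
  are parsed and kept in sequences by default, with an
  `exclude_sensor_prefixes` reader option.
- **Elbow scan**: upper bound = number of classes; if there are fewer
  distinct (bt, et) points, the scan shrinks with a warning; a flat SSE
  curve returns k = 2; curvature ties go to the smaller k.
- **k-means determinism**: fixed `random_state`, 10 restarts,
  best-SSE model kept; SSE is monotone non-increasing in k
  (best-of-restarts), asserted by a property test.
- **Recognition fallbacks**: an empty predicted cluster falls back to
  ranking the full training set (with a warning); a cluster smaller than
  n lets all members vote; a start sensor unseen in training de-noises
  to the start sensor alone (with a warning).
- **Problem sizes in tests**: unit tests run the generator at 5–30 days;
  the end-to-end evaluation and the de-noising batch property use the
  full 60-day default scenario (480 instances), 100 seeds for the batch
  properties — the scale at which per-class importance estimates (n = 60
  per class) are stable relative to the 0.25 threshold.

## Known limitations

- Begin/end annotations are required; unannotated logs cannot be
  segmented (only skipped).
- Linear hour distance penalises activities near midnight; this mirrors
  the similarity formula's definition but is a modelling artefact.
- The instance-based classifier stores and scans all training instances
  per prediction (O(cluster size) edit-distance computations); training
  is cheap, prediction is where the cost lives.
- Macro metrics treat all classes equally; with heavy class imbalance
  the per-fold macro mean can move noticeably for small classes.
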