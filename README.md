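# duoact

Recognition of daily activities for **two residents** in a smart home,
from CASAS-style annotated ambient-sensor event logs.

Homes instrumented with binary motion sensors produce event streams in
which each resident's activities (sleeping, cooking, hygiene, …) leave a
characteristic trail of sensor firings at a characteristic time of day.
With two residents the trails interleave: events triggered by one
resident fall inside the other's activity window and corrupt its sensor
sequence. `duoact` implements an instance-based recognition pipeline
built for exactly this setting, for researchers and practitioners
working with annotated ADL (activities of daily living) logs:

1. **De-noising.** Each activity instance is `a = {bt, et, sq}` — begin
   hour, end hour, and the ordered sensor-ID sequence fired between the
   `begin` and `end` annotations. For every start sensor *s₀* a
   sensor-importance table (SIA) records the fraction of *s₀*-initiated
   activities containing each sensor; a single pass drops consecutive
   duplicates and every sensor whose importance is ≤ a threshold *w*.
2. **Time clustering.** Instances are clustered by k-means on
   (bt, et); the cluster count is picked at the elbow — the point of
   maximal curvature — of the SSE-vs-k curve,
   SSE = Σᵢ Σ_{p∈Cᵢ} ‖p − mᵢ‖².
3. **Similarity voting.** A test instance is assigned to its time
   cluster and scored against each training instance there with

       ratio = w₁(24 − |a.bt − t.bt|)/24 + w₁(24 − |a.et − t.et|)/24
             + w₂·LevRatio(a.sq, t.sq),   2w₁ + w₂ = 1,  2w₁ ≤ w₂

   where LevRatio = (|sq₁|+|sq₂| − ldist)/(|sq₁|+|sq₂|) is the
   token-level Levenshtein ratio (substitutions cost 2). The top-n
   neighbours vote for the label.

Evaluation is stratified five-fold cross-validation with macro-averaged
one-vs-rest accuracy/precision/recall/F-measure. A synthetic
two-resident generator (`duoact.synthgen`) produces CASAS-format logs
with planted time clusters, per-activity sensor signatures and
cross-resident interference, with exact ground truth — so the whole
pipeline is testable without any external dataset.

See `docs/methods.md` for the model's assumptions, parameter defaults
and limitations.

## Worked example

The canonical 12-event log segment contains two overlapping activities;
the intersection events belong to both sequences:

```python
>>> from duoact import *
>>> instances = segment_activities(table1_fixture())
>>> for a in instances:
...     print(a.label, a.bt, a.et, list(a.sq))
Bed_to_Toilet 5 5 ['M004', 'M005', 'M007', 'M001', 'M004', 'M004', 'M007', 'M007']
Sleep 5 5 ['M004', 'M004', 'M007', 'M007', 'M006', 'M007', 'M005', 'M004']
```

Both sequences start with M004, so the SIA row for M004 is built from
two sequences; a sensor present in both scores 1.0, in one scores 0.5:

```python
>>> sia = build_sia([a.sq for a in instances])
>>> sia.table["M004"]
{'M004': 1.0, 'M001': 0.5, 'M007': 1.0, 'M005': 1.0, 'M006': 0.5}
```

De-noising at the default threshold w = 0.25 collapses the duplicate
M004/M007 runs and keeps every sensor (all importances exceed 0.25);
the two activities' sequences still share half their tokens:

```python
>>> list(denoise(instances[1], sia, DenoiseConfig(w=0.25)).sq)
['M004', 'M007', 'M006', 'M007', 'M005', 'M004']
>>> levenshtein_ratio(instances[0].sq, instances[1].sq)
0.5
>>> round(similarity(instances[0], instances[1]), 4)   # w1=0.15, w2=0.7
0.65
```

End to end on a synthetic two-resident log (8 activity classes, 60
days, interference rate 0.3):

```sh
$ duoact simulate --out demo --seed 7
wrote 2890 events / 480 instances to demo
$ duoact evaluate demo/events.txt --out demo/eval --seed 7
macro_accuracy: 1.0000
macro_precision: 1.0000
macro_recall: 1.0000
macro_f_measure: 1.0000
micro_accuracy: 1.0000
```

The scenario's eight activities sit in three time-of-day bands with
disjoint sensor vocabularies, so after de-noising the similarity vote
separates them perfectly — macro F-measure 1.0 means every one of the
480 instances was recognised correctly across the five folds. `duoact
elbow demo/events.txt` prints the SSE-vs-k table and reports the elbow
at k = 3, the planted number of time clusters. Detailed per-class
metrics, per-fold results and the pooled confusion matrix land in
`demo/eval/report.json` and `demo/eval/confusion.csv`, and
`duoact recognize demo/events.txt 0 --n 5` shows one instance's top-5
neighbours with their similarity ratios.

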