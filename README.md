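# implearn

Detecting implicit-learning events from EEG: multiscale-entropy
features, response-time labeling, and artificial-bee-colony feature
selection.

## The problem

In implicit-learning experiments a participant answers four questions
per trial; a hidden rule makes the fourth question answerable from the
first. Once the rule has been (unconsciously) acquired, the fourth
response becomes persistently faster than the second and third — a
behavioral signature — and the EEG over frontal cortex changes in
*complexity* rather than amplitude. `implearn` is a library (plus a thin
CLI) for researchers who want to (a) label trials *fast*/*slow* from
response times, (b) summarize per-question EEG epochs as
multiscale-entropy profiles per channel and frequency band, (c) find the
informative (channel, band) features with a swarm-based wrapper
selector, and (d) quantify whether selection helps classification.

## The methods at its core

**Sample entropy.** For a series of length N, template length m and
tolerance r,

    SampEn(m, r, N) = −log(A / B)

where B counts unordered pairs of length-m templates within Chebyshev
distance r (self-matches excluded, both template sets drawn from the
first N−m positions) and A counts the same for length m+1. Equal counts
give exactly 0 (no complexity). Defaults: m = 2, r = 0.15 × SD of the
epoch.

**Multiscale entropy (MSE).** The series is coarse-grained at scale τ,

    y_j = (1/τ) Σ_{i=(j−1)τ+1}^{jτ} x_i ,  j = 1..⌊N/τ⌋,

and SampEn is recomputed per scale with r held fixed from scale 1. A
3 s epoch at 1000 Hz (3000 samples) coarse-grained at the maximum scale
20 still leaves 150 points. The complexity-versus-scale profile is the
feature.

**TRT labeling.** Response times are smoothed with a centered moving
median (window 5). DRT = smoothed Q4 RT; URT = mean of smoothed Q2 and
Q3 RT. When DRT stays below a lower bound of URT (default: 90% of URT)
for three consecutive trials, those trials receive the
Triple-Response-Time mark and the *fast* label; classes are then
balanced by seeded down-sampling.

**Binary artificial bee colony (ABC).** A food source is a 0/1 vector
over the 45 (channel, band) features (9 frontal channels × 5 bands),
its fitness the 5-fold cross-validated accuracy of a chosen classifier
on the selected columns. Employed bees perturb each source against a
random neighbor (agreeing bits kept, disagreeing bits re-drawn
uniformly) with strict greedy replacement; onlooker bees revisit
sources fitness-proportionally; scout bees re-seed sources abandoned
for more than `limit` attempts. A best-so-far tracker makes the result
monotone.

**Evaluation.** Decision trees (max 100/20/3 nodes), random forest,
kNN (k = 1/3/20 Minkowski, plus cosine) and SVMs (linear, quadratic,
cubic, RBF); stratified 5-fold CV repeated 5 times; confusion-matrix
accuracy/sensitivity/specificity (fast = positive), ROC curves, and a
paired two-sided t-test between with- and without-selection accuracies.

## Worked example

`examples/03_feature_selection.py` plants 5 informative features among
45 on a balanced 175-vs-175 table and runs selection:

```text
all-features 5-fold kNN accuracy: 0.783
selected-subset accuracy:         0.929
features selected: 18 of 45
Jaccard overlap with the planted informative set: 0.28
```

All-features classification is diluted by 40 noise features; the colony
finds a subset whose held-out accuracy is ~0.15 higher. The other
examples show entropy profiles (`01`), response-time labeling with a
planted learning onset (`02`), and the full raw-EEG-to-t-test chain
(`04`). The same stages are scriptable:

```bash
implearn simulate --trials 100 --gap 0.6 --onset 50 --seed 1 --out fixtures/
implearn mse --rec fixtures/recording.csv --events fixtures/events.csv --out mse.csv
implearn label --events fixtures/events.csv --seed 1 --out labels.csv
implearn table --profiles mse.csv --labels labels.csv --out table.csv
implearn select --table table.csv --classifier knn-coarse --seed 1 --out trace.json
implearn evaluate --table table.csv --bits trace.json --out results/
```

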