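# Methods

## Pipeline overview

`implearn` turns a multichannel EEG recording and a per-question event
table into a statistical verdict on whether complexity-based features
distinguish behaviorally *fast* (post-learning) from *slow* trials:

1. **Conditioning** (`io`): zero-phase 4th-order Butterworth band-pass
   0.5–50 Hz plus a Q = 30 notch at 60 Hz. Zero-phase (forward–backward)
   filtering preserves epoch timing at the cost of squaring the
   magnitude response, so band edges sit at −6 dB rather than −3 dB.
   Independent-component artifact removal is a documented upstream
   hook, not part of the package: inputs are assumed artifact-cleaned.
2. **Band splitting** (`io`): delta 0.5–4, theta 4–8, alpha 8–13, beta
   13–30, gamma 30–50 Hz (gamma capped by the low-pass). These are
   standard clinical conventions; the mapping is fully configurable.
3. **Epoching** (`io`): epoch (t, q) spans question q's onset up to the
   next question's onset (next trial's first onset after q = 4;
   recording end for the final trial), half-open on 0-based sample
   indices, so epochs tile each trial exactly. Responses outside the
   3 s window are kept as epochs but flagged missing for labeling.
4. **Multiscale entropy** (`entropy`): see below.
5. **TRT labeling** (`labeling`): see below.
6. **Assembly** (`features`): one row per labeled trial from the fourth
   question's epochs by default (the question governed by the hidden
   rule; all four concatenated on request), one column per (channel,
   band, scale). Rows containing undefined entropy values are dropped
   with a logged count and classes re-balanced.
7. **Selection** (`select`) and **evaluation** (`evaluate`).

## Sample entropy and its conventions

SampEn(m, r, N) = −log(A/B) with Chebyshev matching and the
Richman–Moorman counting convention: templates of both lengths start at
the first N − m positions, pairs are unordered, self-matches excluded,
distance ≤ r inclusive. Consequences relied on elsewhere:

* a constant input has A = B and SampEn exactly 0;
* A = 0 (no m+1 matches) leaves the ratio undefined; the value is NaN,
  propagated and dropped at assembly with a logged count, rather than
  substituted by an arbitrary cap that would distort classification;
* SampEn is non-increasing in r.

Defaults m = 2, r = 0.15 × SD; the SD is the population formula
(divide by N) so results are bit-stable, and the 1/(N−1) difference is
negligible at the N ≥ 150 the scale cap guarantees. The logarithm is
natural (nats). r is computed once from the scale-1 epoch and reused at
every scale: recomputing per scale would conflate the variance
reduction of coarse-graining with genuine complexity change. The
maximum scale 20 keeps ⌊3000/20⌋ = 150 points at the coarsest scale for
a 3 s, 1000 Hz epoch, inside the accepted 100–400-point reliability
range. The optimized counter is vectorised in row blocks (O(N²) time,
O(chunk·N) memory) and is tested integer-for-integer against an
exhaustive pair-enumeration oracle.

## TRT labeling

Moving-median smoothing (window 5, centered, truncated at the series
edges so no trial is discarded) is applied per question across trials.
DRT = smoothed Q4; URT = (smoothed Q2 + smoothed Q3)/2. A trial is
*below* when DRT < bound(URT); the third and all later trials of each
maximal below-run of length ≥ 3 receive the TRT mark (the mark is given
when the three-consecutive criterion completes). Marked trials are
fast, others slow; trials missing Q2/Q3/Q4 are excluded and break runs
(the conservative choice: an unobserved trial cannot attest a
consecutive run).

**Bound rule.** Two readings of a "90% lower bound of URT" are
implemented:

* `fraction` (default): bound = confidence × URT.
* `normal_lower`: bound = rolling mean(URT) − z(confidence) ·
  rolling sd(URT)/√n over a centered 5-trial window, z(0.90) = 1.2816.

The confidence-limit variant is the textbook construct, but its margin
shrinks with √n and sits well inside the trial-to-trial dispersion of
the *smoothed* DRT series, so under the null (no speed-up) it marks
roughly a third of trials and, with the run correlation that smoothing
induces, produces spurious TRT runs in essentially every session. The
fractional threshold scales with the response-time level, keeps the
null false-mark rate near zero (typical RT dispersion is well under 10%
of the RT level), and a genuine speed-up of a few hundred milliseconds
still crosses it; it is therefore the default. Note the trade-off: the
fractional rule is invariant to *rescaling* all RTs, the confidence
rule to *shifting* them. On noiseless planted data the first mark lands
exactly at onset + 2; at a 5-sigma effect it lands within ±2 trials.

Class balancing down-samples the majority class uniformly at random
with an explicit seed (otherwise the selection would be
irreproducible).

## Feature encoding and the bee colony

One selection bit per (channel, band) pair — 9 frontal channels (AF3,
AF4, F3, F4, F5, F6, F7, F8, FZ) × 5 bands = 45 bits — each bit gating
that pair's full profile over scales 1..20 (900 columns when all bits
are set). Bit-per-pair keeps the search space meaningful for a wrapper
selector; per-scale bits (900-dimensional) are deliberately out of
scope.

The colony: `n_sources` food sources, initialised as fair independent
coin flips (all-zero draws redrawn), each evaluated once. Per
iteration: employed phase (each source forms a candidate against a
random other source — agreeing bits kept, disagreeing bits re-drawn
uniformly, 0 if φ ≤ 0.5 — and replaces it only if *strictly* better,
else its abandonment counter grows; strictness keeps counter progress
well-defined), onlooker phase (`n_sources` roulette draws with
P_i = fit_i/Σfit, same greedy step), scout phase (counter strictly
greater than `limit` → fresh random source). Defaults n_sources = 20,
limit = 10, max_iter = 50. Fitness = stratified 5-fold CV accuracy with
a fixed fold seed, hence deterministic, hence safely memoised by bit
pattern; an all-zero selection is unclassifiable and scores 0. The
best-so-far tracker is outside the population, so the reported optimum
is monotone in iteration by construction. The classic real-valued
neighbor update (current + φ·(current − neighbor)) is documented for
context but not used: food sources here are binary and the keep-or-
randomize rule is the operative binary specialisation.

## Classifiers, folding, metrics, statistics

All estimators are scikit-learn: decision trees bounded to 100/20/3
leaf nodes (fine/medium/coarse), a 100-tree random forest, kNN with
Minkowski distance at k = 1/3/20 plus a cosine-distance variant
(neighbor count unspecified alongside the 1/3/20 family; the common
toolbox preset of 10 is used), and C-SVMs with linear, quadratic, cubic
and Gaussian-RBF kernels. kNN and SVM inputs are z-scored with
statistics fit on training folds only (distance- and margin-based
learners are scale-sensitive; train-only fitting avoids leakage); trees
are not scaled.

Folds are stratified (balanced 175/175 classes make that the natural
reading of "5-fold"); a class smaller than k raises rather than
silently degrading. Repeated evaluation derives one seed per repeat,
pools each repeat's held-out predictions into one confusion matrix
(mean-of-folds available via flag), and summarises best/quartiles/
median/mean/SD over repeats. Fast is the positive class throughout, so
sensitivity reads "fast events recognised". ROC curves pool held-out
scores (probability or decision margin) across folds and sweep all
unique thresholds; a median curve over repeats is interpolated on a
common FPR grid.

The with/without-selection comparison is a two-sided t-test, default
*paired* over the matched CV repeats with df = n − 1 (df = 4 at five
repeats); the pooled-variance independent-samples test (df = 2n − 2) is
available via `mode="independent"`. Degenerate zero-variance inputs
return t = 0, p = 1 (identical samples) rather than NaN.

## Synthetic data: what it emulates, what it does not

`gen_rt` emulates the behavioral series: four RTs per trial around a
1.5 s base with Gaussian noise (default sd 0.1 s), question onsets 3 s
apart with a random 0–1 s inter-trial delay, and a persistent Q4
speed-up of `rt_effect` (default 0.5 s) from `learning_onset` on,
clipped to the (0, 3] s response window.

`gen_epochs` builds a continuous recording as a sum of per-band
band-limited noise components, variance-normalised per question
segment. In the informative (channel, band) pairs, fast-class segments
(trial ≥ onset + 2, where the TRT mark can land) carry a
`complexity_gap` fraction of their power as a band-center sinusoid and
are re-normalised: regularity rises, entropy falls, power is unchanged,
so the class difference lives where MSE looks and not in variance. An
autoregressive lag-one tilt was the first candidate manipulation and
was rejected on measurement: after a 4th-order band-pass the within-
band AR tilt changes MSE by under 0.1 SD at every scale (the filter's
own spectral shaping dominates), whereas oscillatory regularity
survives filtering with 2–3.5 SD effects.

`gen_feature_table` plants the same contrast directly at the feature
level: every profile follows a common decaying base curve plus i.i.d.
Gaussian noise (sd 0.30), with the fast class offset by `gap` in the
informative features. The defaults — 175 rows per class (the balanced
design size), 5 informative of 45 features, gap 0.13 — were calibrated
once so the all-features kNN baseline lands near 0.84, inside the
0.75–0.87 range realistic for balanced two-class EEG problems, leaving
visible headroom for selection; they are not tuned per experiment.

What passing tests on these fixtures shows: the pipeline detects
complexity differences of plausible effect size, the labeler localises
a planted onset, and the selector finds planted subsets and improves
held-out accuracy significantly. What it does not show: performance on
real EEG with artifacts, volume conduction, non-stationarity,
inter-subject variability, or entropy differences of unknown effect
size; absolute accuracies on synthetic tables carry no information
about any real dataset.

## Problem sizes used in tests and the acceptance script

The full chain is exercised at reduced scale — tens of trials, three
channels, beta/gamma bands at 250 Hz, 1.2 s epochs, scales 1..5 — which
preserves every statistical mechanism while keeping a complete
preprocess → entropy → label → assemble → select run to seconds. The
selection experiments use the feature-level generator at full design
size (175/class, 45 features, 900 columns) with a compact colony
(8 sources, limit 5, 15 iterations), which reliably finds
high-accuracy subsets on these tables. The acceptance script runs ten
such seeded experiments plus the arithmetic, entropy, labeling and
convergence checks in a few minutes on one CPU.

## Numerical choices and degenerate inputs

* Epoch boundaries: `round(onset × fs)`, shared between consecutive
  epochs, so per-trial epochs tile exactly.
* Coarse-graining drops the trailing remainder (length ⌊N/τ⌋).
* SampEn ties: distance exactly r counts as a match (inclusive).
* Candidate ties in the colony never replace (strict improvement).
* Roulette probabilities with all-zero fitness fall back to uniform.
* `mask_features` intersects with present columns, so masking is
  idempotent; a zero-column table is rejected at classification time
  with a clear error.
* Seeds: every stochastic step takes an explicit seed; derived seeds
  are kept below 2³¹.

## Known limitations

* ICA/artifact handling is out of scope by design; raw clinical data
  needs upstream cleaning.
* The moving-median edge policy (truncated windows) slightly biases the
  first and last two trials; the planted-onset recovery tolerance of
  ±2 trials reflects exactly this.
* The colony is the static textbook variant; no adaptive limits or
  dimension-aware perturbation schedules.
* Band power summation reconstructs the broadband signal only
  approximately (~11% RMS residual interior to the band edges): the
  five Butterworth bands are not a perfect-reconstruction filter bank.
* EDF support covers the standard single-rate layout via MNE;
  EDF+ annotations are ignored.
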