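# Methods

This note documents the models, estimators and numerical choices behind
`eegreduce`, and what the synthetic validation does and does not establish.

## Pipeline model and assumptions

The pipeline treats seizure detection as window-level binary
classification.  Each 1-s window of a 19-channel recording is one sample;
all ictal subtypes (complex partial, electrographic, video-detected) are
merged into a single positive class.  No artifact removal or filtering is
applied: the feature set is expected to cope with raw (z-scored) signal.
Windows are non-overlapping, and the trailing remainder shorter than one
window is discarded, so a recording of S samples yields exactly
`floor(S / (fs * window_seconds))` windows.

Normalisation is per channel and per continuous recording, never pooled
across the train/test split, so no statistics leak between splits.  A
per-window normalisation variant exists behind a flag for sensitivity
analysis.  Constant channels are a hard error (they cannot be z-scored and
indicate a dead electrode or a format problem).

## Feature definitions and numerical choices

* Standard deviations and variances use the N−1 denominator throughout.
* The signal derivative is realised as first differences without
  sampling-rate scaling.  Mobility and Complexity are ratios of such
  quantities, so any constant fs factor cancels; Activity and Energy keep
  the signal's units squared.
* Quantiles (quartiles, P10/P90, median) interpolate linearly between order
  statistics.
* The mode of a continuous-valued window is estimated by a half-sample mode:
  recursively keep the narrowest half of the sorted sample until ≤3 points
  remain.  Width ties are resolved twice (leftmost and rightmost interval)
  and the two estimates averaged, which makes the estimator deterministic
  *and* exactly unbiased on mirror-symmetric samples.  When repeated values
  exist the exact discrete mode is used instead (smallest value on tied
  counts).
* The zero-crossing feature excludes sample pairs containing an exact zero.
  The default (`conventional`) counts sign changes, matching the reading
  that high values indicate high frequency; an `as_printed` mode returning
  the complement `(K−1) − C` is retained because the formula also admits
  that literal reading.
* Degenerate windows (zero variance, `P90 == P10`, zero-variance first
  difference) make individual features undefined.  The scalar API raises a
  typed error naming the condition; the matrix extraction path records NaN,
  logs the count, and modelling drops affected windows explicitly — values
  are never silently zeroed.

## Classifier suite

Tree ensembles (random forest, XGBoost) are grid-searched over
n_estimators {5, 100, 300, 500} × max_depth {1, 3, 5, 10, 50}; the decision
tree over the depth grid alone.  Non-tree families carry deliberately small
grids: neighbour count {1, 3, 5, 7} for kNN, fixed RBF kernel and default C
for the SVM, default-regularised logistic regression, Gaussian naive Bayes
without tuning.  Per-family grid overrides are plain config, since
reasonable deployments may want points outside the canonical grid.

Cross-validation uses 5 stratified folds (shuffled with the run seed); the
recorded training score is the best grid point's mean CV accuracy.  Model
selection is argmax of test accuracy with ties broken by higher CV training
accuracy, then by the fixed family order listed above — fully deterministic
under a fixed seed.  Class 1 (ictal) is the positive class; reports list
per-class precision, recall and F1 in the order (interictal, ictal), as
percentages rounded to two decimals.

## Shapley attributions

Attribute importance is the mean absolute per-sample Shapley attribution,
computed by default on the test split (a train-split switch exists).  Three
engines:

* **Path-dependent tree Shapley** for decision trees, random forests and
  XGBoost boosters.  Conditional expectations under a feature coalition
  follow the training cover stored at each split; the polynomial-time path
  algorithm distributes each leaf's value over the features on its path.
  For boosters the trees are parsed once and evaluated in float64 — the
  built-in float32 contributions accumulate errors around 1e-5 on deep
  ensembles, which would mask genuine additivity violations.  Correctness
  is tested against exhaustive subset enumeration on small trees and
  against xgboost's own contributions at float32 tolerance.  Attributions
  are on the log-odds margin scale for boosters and the class-1 probability
  scale for sklearn trees.
* **Permutation sampling** for any other model: per permutation one
  background row (from up to 100 background samples) is shared across all
  evaluated rows, so the telescoping sum keeps local accuracy exact rather
  than approximate.  Default 20 permutations, seeded.
* **`tree32`**, the raw xgboost fast path, kept for large-scale runs.

Local accuracy (`base + Σφ = margin` per sample) is asserted at 1e-6 on the
margin scale; the float64 tree route achieves ~1e-14.

Incremental models reuse the winning family's hyperparameters for the
phase-1 top-k series (only phase 2 re-searches the grid, on the reduced
matrix).  Recurrence selection counts features and channels among the
top-20 attributes; ties at equal count are broken by the summed mean-|φ| of
the tied item's attributes, then lexicographically, and the break is
logged.  If fewer distinct features or channels appear in the top-20 than
requested, the selection is the full cross product of what exists.

## Synthetic study condition

The generator emulates the statistical shape of the clinical datasets this
pipeline targets: 19 named 10-20 channels at 500 Hz, pre-split
train/test, whole recordings labelled interictal or ictal.

* Background on every channel is 1/f^β Gaussian noise (β = 1, std 20 µV)
  with sporadic artifact transients (raised-cosine bumps of 0.2–0.4 s,
  ~4× background amplitude, 0.05 per channel-second) at identical rates in
  both classes.
* Ictal recordings add a rhythmic spike-wave component — a 3 Hz oscillation
  with four 1/h-decaying harmonics, unit-std normalised — only on the
  configured focal channels (default Fz, C4, T5).  Its amplitude is
  (gain−1)× background std (default gain 5), re-drawn every second from
  U(0.5, 1.5) and dropped to near-quiescence U(0, 0.2) with probability
  0.3: electrode involvement waxes and wanes, so no single channel is
  sufficient and the classifier must pool the focal set — the property that
  makes recurrence-based channel recovery a meaningful test.  With gain 1
  the ictal class is exactly background and classifiers sit at chance.
* Every draw comes from a dedicated substream spawned per split, class,
  segment and channel, so output is bit-identical under a fixed seed,
  train/test are independent, and the focal effect is exactly local
  (non-focal channels have identical distributions in both classes; note
  that windows within one 1/f record share its slow components, so the
  record, not the window, is the independent replicate for such checks).

Reference problem sizes are 300 s per class of training signal and 60 s per
class of test signal in 60-s records — 600/120 windows — which keeps a full
suite-plus-two-phase run around a minute on one CPU while leaving all
selection and recovery behaviour intact.

**What passing on synthetic data does not show.**  The generator has no
volume conduction (channels are independent), no inter-patient variability,
no seizure evolution beyond second-scale amplitude modulation, and its
artifacts are far simpler than real blink/EMG contamination.  Planted
effects at gain 5 are strong; real interictal/ictal contrasts are weaker
and the reported synthetic accuracies (≈98–100%) are therefore upper bounds
on behaviour, not forecasts of clinical performance.  The recovery results
show the *selection machinery* works when ground truth exists; they say
nothing about whether clinically selected channels generalise across
patients.

## Known limitations

* The path-dependent tree engine is pure Python; ranking a 500-tree
  depth-50 forest on thousands of evaluation rows is slow.  The `tree32`
  fast path or a capped evaluation set are the practical escape hatches.
* The MAT-file loader discovers arrays by a configurable name pattern
  (`train_<label>_NN` by default) because the public release does not
  document its internal variable names; real downloads may need a custom
  pattern and a transpose flag.
* Shapley values assume feature independence when read as importances;
  spatially adjacent electrodes are correlated, so attribute importances
  on real montages should be read as model-relative, not causal.
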