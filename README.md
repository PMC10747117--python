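# eegreduce

Explainability-driven channel and feature reduction for EEG seizure
detection.

Scalp EEG review for epilepsy is a binary discrimination problem at heart:
is a given stretch of signal *interictal* (between seizures) or *ictal*
(during a seizure)?  Classifiers built on many electrodes and many features
do this well but are opaque and expensive to deploy.  `eegreduce` implements
a two-phase pipeline that starts from a full 10-20 montage and a broad
time-domain feature set, and uses Shapley additive attributions to shrink
the model to a handful of attributes on a handful of electrodes — small
enough to interpret clinically and to run on wearable hardware — while
keeping the full model's accuracy.

It is aimed at clinical-neurophysiology and biosignal-ML researchers who
want a transparent, fully seeded reference implementation of
attribution-based channel selection, including a synthetic EEG generator
with planted focal channels so every stage can be validated without access
to clinical recordings.

## Method

**Windowing and features.** Each recording (19 channels — Fp2, Fp1, F8, F4,
Fz, F3, F7, A2, T4, C4, C3, T3, A1, T6, P4, P3, T5, O2, O1 — at 500 Hz) is
z-scored per channel (N−1 denominator), cut into non-overlapping 1-s
windows, and labelled 0/1 after merging all seizure subtypes into one ictal
class.  On every channel window *x*₁…*x*_N, 13 time-domain descriptors are
computed:

* order statistics: mean x̄, Median, Maximum, Minimum, amplitude
  (x_max − x_min);
* Hjorth parameters: Activity = Σ(xᵢ − x̄)²/(N−1),
  Mobility = √(var(Δx)/var(x)), Complexity = mob(Δx)/mob(x), with Δx the
  first differences;
* Energy = (1/N)Σxᵢ² and RMS = √Energy;
* a percentile coefficient of kurtosis (Q₃ − Q₁)/(2(P₉₀ − P₁₀));
* Pearson mode skewness (x̄ − mode)/std, with a deterministic half-sample
  mode for continuous data;
* a zero-crossing count (sign changes of consecutive samples, pairs
  containing an exact zero excluded).

An *attribute* is one feature on one channel, named `<Feature>_<Channel>`
(e.g. `Minimum_Fz`); 19 channels × 13 features give 247 attributes per
window.

**Phase 1.** Seven classifiers (decision tree, kNN, logistic regression,
Gaussian naive Bayes, random forest, XGBoost, RBF SVM) are grid-searched —
tree ensembles over estimators {5, 100, 300, 500} × depth {1, 3, 5, 10, 50}
— and the family with the highest test accuracy is kept.  Its attributes
are ranked by mean |SHAP| (per-sample Shapley attributions of the model
output), and nested models on the top-1 … top-20 attributes trace an
accuracy-vs-size curve.

**Phase 2.** Among the top-20 attributes, the 4 most recurrent features and
5 most recurrent channels are crossed into 20 reduced attributes; the
winning family is re-tuned on that matrix, re-ranked, and a second 20-point
curve identifies the smallest model (≤6 attributes in practice) that holds
the line.

Shapley attributions are computed by a path-dependent tree-Shapley
implementation evaluated in float64 (local accuracy `base + Σφ = margin`
holds to machine precision; verified against exhaustive subset enumeration
and against xgboost's built-in contributions), with a seeded
permutation-sampling estimator for non-tree models.

## Worked example

Run the full two-phase experiment on synthetic EEG with three planted focal
channels (Fz, C4, T5):

```bash
cat > config.yaml <<EOF
synth:
  train_seconds_per_class: 120.0
  test_seconds_per_class: 60.0
  record_seconds: 30.0
  seed: 5
seed: 5
EOF
eegreduce run-all --config config.yaml --out out/
```

prints (about a minute on one CPU):

```
phase-1 winner: random_forest
phase-1 accuracy (full): 100.00%
phase-2 accuracy (20 attributes): 100.00%
phase-2 accuracy (best k<=6: 6 attributes): 98.33%
```

The winner here is a random forest: with 240 training windows several
families tie at 100% test accuracy and ties resolve by cross-validated
training accuracy, then by a fixed family order.  `out/phase1_ranking.csv`
holds the attribution ranking; its head is dominated by rhythm-shape
features on the planted channels:

```
 rank        attribute  importance
    1 Zero_crossing_T5    0.020470
    2      Mobility_Fz    0.019817
    3    Complexity_Fz    0.016953
    4    Complexity_C4    0.016526
    5    Complexity_T5    0.015768
```

`out/reduction_report.json` records the recurrence selection — features
{amplitude, Complexity, Mobility, Zero crossing} on channels
{Fz, T5, C4, F3}, i.e. all three planted channels recovered plus one
spurious neighbour — and both per-k accuracy curves.  The phase-2 curve
climbs from 81.67% with a single attribute to 98.33% with six: the planted
seizure activity is detectable from a few attributes on the focal
electrodes alone, which is the point of the method.

Real recordings in the supported MAT layout or delimited text load through
`eegreduce.io.load_ubmc_dataset` / `load_delimited` and run through the
same commands with `source: ubmc` in the config.

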