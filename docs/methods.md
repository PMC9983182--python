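# Methods

This note documents the models, procedures and design choices behind
`augsplit`: what the framework computes, what its synthetic data do and do
not emulate, and where numerical conventions had to be fixed.

## The experimental design being modeled

A balanced two-class image-classification benchmark is evaluated by
stratified five-fold cross-validation.  In each fold the test part is one of
five non-intersecting stratified fifths of the data; the remaining four
fifths are shuffled and divided 3:1 into training and validation, again
per class.  Eight-fold augmentation applies the dihedral group of order 8
(rotations by 0°/90°/180°/270° and their horizontal flips) to each image —
a lossless pixel permutation, never interpolation.  The six model-building
ways (A–F, see README) differ only in *which* subsets are augmented and
*when* relative to the two splitting steps; ways A–E can additionally be
scored on either the original or the augmented test set, giving 11
evaluation configurations.

Ways E and F split *after* augmenting, at the individual-image level.  That
is deliberate: it is precisely the practice that places derivatives of one
parent into different subsets, and the leakage audit counts, per subset
pair, the parents whose orbit spans both.  Structurally, ways A–D can leak
nothing, way E can leak only between training and validation, and way F can
leak into the test set itself.

## Splitting conventions

Stratified k-fold: within each class, membership is shuffled by the seed
and dealt into k parts whose sizes differ by at most one; *which* parts
receive the remainder is also seed-driven, so no part is systematically
larger.  The 3:1 split is per class by largest remainder: training receives
⌊3n/4⌋ records, validation ⌊n/4⌋, and the single leftover record (when n is
not a multiple of 4) goes to the side with the larger fractional remainder,
with a seeded coin on the exact tie at n ≡ 2 (mod 4).  The 3:1 rounding is
applied per class rather than globally; the two conventions differ only by
a record or two but the per-class one keeps stratification exact.

All randomness descends from one master seed through tagged
`SeedSequence`-derived sub-seeds (per stage, per fold, per epoch), so any
single fold or epoch is reproducible in isolation and identical
configurations are bit-reproducible end to end.

## Training schedule

The harness trains any classifier exposing `train_epoch` /
`predict_proba` / `get_state` / `set_state`.  Defaults: mini-batches of 10
images, momentum SGD (momentum 0.9, learning rate 1e-4, L2 factor 1e-4),
training set reshuffled every epoch, at most 50 epochs.  After every epoch
the validation accuracy at the 0.5 threshold is computed; an epoch
"improves the model" only if it strictly exceeds the best accuracy so far,
and training stops after 5 consecutive non-improving epochs (the patience)
or at the epoch cap.  The model returned is the best-validation
checkpoint, not the last epoch's — with a noisy validation trace the last
epoch is usually past its best.  A probability exactly at the threshold
counts as a positive call.  Training time is recorded as wall-clock
seconds and used only relatively (for the time-cost correlation); no test
asserts absolute times.

## Statistics layer

* **Pooled proportions.** Accuracy, sensitivity and specificity are
  micro-averages of the per-fold confusion counts (equivalent to one
  confusion matrix over all folds' predictions).  Their 95% CIs are
  Clopper–Pearson exact intervals with the formula's numerator and
  denominator as successes and trials (computed via
  `scipy.stats.binomtest(...).proportion_ci(method="exact")`, with the
  conventional bounds 0 and 1 at the extremes).
* **Pooled ROC AUC.** Probabilities from all folds are pooled before the
  ROC analysis; this penalizes models whose calibration drifts across
  folds, unlike averaging per-fold AUCs (a unit test constructs two
  perfectly-separating folds with disjoint probability ranges whose pooled
  AUC is < 1).  The AUC is the Mann–Whitney statistic (ties count one
  half).  The default CI is DeLong's variance estimate; an
  "exact-binomial" mode treats the AUC as a proportion of concordant
  positive×negative pairs (rounded to the nearest pair count) and applies
  Clopper–Pearson.  The exact-binomial mode is a deliberately coarse
  convention — pair counts are not independent trials — and is provided
  for comparability, not inference.
* **Effort summaries.** Per-fold epoch counts and training times get
  mean ± t(1−α/2, k−1)·sd/√k intervals (4 degrees of freedom at k = 5).
* **Time-cost-effectiveness.** Within one classifier stratum, each
  testing metric is correlated (Pearson, two-sided p from the t
  distribution with n−2 df) against the natural log of mean training time,
  with a fitted line whose slope expresses points-per-log-second.  The log
  is natural; base only rescales the slope, never r or p.  Callers must
  exclude the augment-first (way F) groups and non-augmented-test metrics
  first — `filter_time_cost_groups` does exactly that and leaves 5 groups
  per classifier (20 in a four-classifier matrix).  No multiple-testing
  correction is applied; p-values are reported raw.

## The synthetic-data generator

The generator emulates the *statistical* structure that makes augmentation
placement measurable, with parametric textures instead of photographs.
Each 32×32 grayscale image (side and all strengths configurable) is

    0.5 + 0.12·( s·(texture + 0.25·ring) + f·fingerprint + a·nuisance ) + noise,

clamped to [0, 1]:

* **texture** — isotropic Gaussian random field, unit variance, correlation
  length 1.8 px for the negative (inflammation-analog) class and 0.9 px for
  the positive (carcinoma-analog) class: the malignant analog is rougher.
* **ring** — a cosine of the distance from the image center (period 8 px),
  sign-flipped between classes.  Radius is preserved by every dihedral
  transform of a square grid, so this first-order cue is *exactly*
  orientation-invariant; it is what lets a small classifier learn something
  from the 120 training images of way B, standing in for the strong,
  directly visible class differences of real histology.
* **fingerprint** — a per-image random field averaged over its own 8
  dihedral transforms, hence identical in every orbit member.  This is the
  leakage mechanism: a model that partly memorizes training images will
  recognize their orbit mates wherever the split put them.  At the default
  strength, ≥ 95% of derivatives have their nearest pixel-space neighbor
  inside their own orbit (a tested property).
* **nuisance** — a label-independent smooth horizontal banding (anisotropic
  Gaussian field, σ = (1.2, 8) px), the analog of illumination gradients
  and scanning-direction artefacts in real photographs.  Both classes share
  it, so it carries no class information and the *class-conditional class
  signal* remains dihedral-invariant; but a model trained only on originals
  adapts its features to the banding's orientation and scores lower on
  rotated inputs.  Without such a component that deficit would be a
  mathematical null: for any fixed model f and test draw X from an exactly
  invariant law, t(X) ~ X implies equal expected accuracy on transformed
  and original test sets.  The oriented nuisance is therefore load-bearing
  for the two findings about augmented *evaluation* sets (augmenting only
  the validation set lowers validation accuracy; with unaugmented training,
  augmented-test metrics are lower).

Defaults (signal strength 1.0, fingerprint 1.2, nuisance 4.0, noise sd
0.02) were fixed once, during design, to place the no-augmentation
baseline (way B) in the informative mid-range — pooled accuracy roughly
0.65–0.75 at 200 originals — where the placement effects are neither
saturated nor drowned.  The composite amplitude deliberately drives some
pixels into the clamp; the saturation is pointwise, so it commutes with
every dihedral transform and preserves all invariances.

What the generator does **not** emulate: stain color (images are
grayscale), slide- or patient-level structure (records are independent;
the real study also split at the image level), class imbalance, or any
"invalid"/reject category.  Passing tests therefore demonstrate the
placement and leakage phenomenology, not performance on real tissue.

## Reference classifier

A deliberately small convolutional network in pure numpy: one bank of 8
3×3 filters (zero-padded), ReLU, 2×2 average pooling, and a dense sigmoid
head on the 16×16×8 feature map, trained with the harness's momentum SGD.
Inputs are centered and scaled by a fixed gain of 12, and the filter bank
is initialized at scale 0.35 — both chosen so the model trains to its
plateau within tens of epochs at the schedule's small learning rate, the
way a pre-trained network fine-tunes quickly.  The convolution reads the
texture cue, the spatially-resolved dense head supplies the (limited)
memorization capacity that makes fingerprint leakage visible.  Patch
features are cached per input array, so an epoch over a cached training
set is a single pair of matrix products per mini-batch; a way-F fold
(4 800 training images) trains in a few seconds on one CPU.  A pixel-space
logistic regression (`PixelLogistic`) is provided as the fast tier for
tests and as the simplest contract example; stubs with scripted validation
traces exercise the early-stopping rule exactly.

## The replicated placement study

`run_placement_study` repeats all six ways over independent replicate
seeds — fresh dataset, splits and initialization per replicate — at the
generator defaults (200 originals of 32×32) with five folds.  Directional
findings are evaluated on paired per-seed differences with an exhaustive
one-sided sign-flip test (all 2^n sign assignments; 10 replicates give a
floor of p ≈ 0.001).  The acceptance suite asserts, at 10 seeds and
α = 0.05: F's test accuracy above E's; E's validation accuracy above its
own test accuracy; C/D/E validation accuracy above B's; A's below B's;
plain-test accuracy above augmented-test accuracy when training is
unaugmented; and an augmented-test CI width below half the plain-test
width (the √8 trials effect).  Problem sizes throughout (200 originals for
the study, 500 for the leakage audit, 3 replicate seeds in the acceptance
script vs 10 in the test suite) are the package's chosen desk-scale
conditions: large enough for every effect to be measurable, small enough
to run on a single CPU in minutes.

## Known limitations

* The weakest effect at desk scale is the augmented-test deficit of
  unaugmented-training models (ways A/B).  It is conditional on the
  baseline model actually learning, and with 120 training images and a
  40-image validation set the early-stopping rule occasionally returns a
  luckily-validated but untrained checkpoint, washing the effect out in
  some replicates; the directional test on it is under-powered at ten
  seeds and can fail even though the per-replicate differences are
  positive in most runs.
* The synthetic effects are qualitative stand-ins; effect *sizes* on real
  histopathology depend on dataset scale, pretraining and architecture and
  are out of scope here.
* Image-level splitting reproduces the modeled design faithfully, but in
  clinical practice slide- or patient-level grouping is the sounder
  protocol; the framework audits orbit-level leakage only.
* The exact-binomial AUC interval is a convention, not a calibrated
  procedure (see above); DeLong is the default for a reason.
* Validation accuracies are reported at the best-validation checkpoint, so
  they carry the usual optimistic selection bias of early stopping; the
  study's comparisons are between configurations measured identically, so
  the bias largely cancels in the paired differences.
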