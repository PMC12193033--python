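# Methods

## Model and procedure

The package implements a stacked ("transfer") feature scheme for
wearable-sensor exercise recognition. Each observation is one 9-channel
sensor row (tri-axial accelerometer, gyroscope, magnetometer at 25 Hz) with
one of K=8 exercise labels. Two base learners are fitted on training rows
and their internals become the features of a second-stage classifier:

1. **Probabilistic block.** A Random Forest (10 trees, depth cap 10,
   entropy splits, seeded) supplies the averaged per-tree class
   distribution `P(c|x) = (1/N) Σᵢ Pᵢ(c|x)` — K columns per row, each row a
   probability vector (sums to 1 within 1e-9, asserted).
2. **Temporal block.** A single-layer LSTM with a softmax classification
   head is trained on length-`W_len` windows of consecutive rows
   (supervision: the window's final-row label). After training the head is
   discarded and the final hidden state `h_T` — the standard fixed-length
   sequence embedding — provides H columns per row.

The second-stage classifier (RF, decision tree, multinomial logistic
regression, or Gaussian naive Bayes) is trained on the concatenation
`[RF block | LSTM block]`, in that fixed column order.

## Leakage and the two transform modes

In-sample stacking — using a forest's probabilities for the very rows it
was trained on — leaks label information into the features: on hard
synthetic data the training-set accuracy of a downstream classifier on
in-sample features exceeds its leakage-safe cross-validated accuracy by
~0.5 (recomputed by `scripts/acceptance.py`). The transformer therefore
has two modes:

* `in_sample` — extractors fitted on all training rows, applied directly;
  replicates the original scheme and documents its optimism.
* `out_of_fold` (default) — the training rows are partitioned into
  stratified folds (5 by default); each row's features come from extractors
  fitted on the other folds. New (held-out) data is transformed with the
  *average* of the fold extractors' outputs, the stacked-generalisation
  convention, so held-out features follow the distribution the second-stage
  model was trained on. All fold extractors share the full-fit
  configuration and seed: for the RF block this is immaterial, but for the
  LSTM block a shared initialisation keeps the fold-wise hidden-state
  representations mutually aligned — with independent initialisations the
  hidden coordinates of different fold models are arbitrary rotations of
  one another and the averaged features degrade.

Transforming a held-out partition goes through `transform(X)`, which takes
no label argument at all; test labels cannot reach feature construction by
construction.

## LSTM implementation and training recipe

The cell is the standard gate block (forget, input, output gates and tanh
candidate state) acting on `[h_prev, x_t]`, implemented in numpy as a pure
function (`lstm_cell_step`) plus a batched forward/backward
(backpropagation through time). Training uses Adam (β₁=0.9, β₂=0.999,
ε=1e-8) on categorical cross-entropy. Defaults: hidden size H=32, window
length W_len=1, 10 epochs, batch 256, learning rate 0.01, uniform(−k, k)
initialisation with k=1/√H. The backward pass is verified against central
finite differences in the test suite.

* **W_len=1 default.** The scheme classifies individual rows, and the
  evaluation counts (supports) must equal row counts; each row is treated
  as a length-1 sequence. Longer sliding windows are supported: a row's
  window is itself plus the `W_len−1` preceding rows, edge-padded by
  repeating the first row, so n inputs always yield n feature rows.
* **Learning rate 0.01** (rather than Adam's common 0.001) because the
  training runs are short (10 epochs) and the inputs are standardised;
  convergence at desk scale is the goal, not fine-tuning.
* Training is seeded and bit-reproducible on a fixed platform/BLAS; exact
  cross-platform equality of trained weights is not guaranteed.

## Downstream classifiers

Fitting delegates to scikit-learn with the tuned defaults: RF(10 trees,
depth 10, entropy, seed 0), DT(no leaf cap, zero impurity-decrease floor),
LR(softmax/multinomial with L2 at C=1.0, 200 iterations, seed 0 — the
modern resolution of an "auto" multi-class setting), GNB(no prior
override, variance smoothing 1e-9). The decision tree accepts a seed
(default 0) for run-to-run reproducibility even though its reference
configuration leaves the state unset. Two formulas are additionally
implemented natively so they are directly testable: the per-feature
Gaussian likelihood and the binary logistic probability; a native
log-space GNB scorer (log priors + summed log likelihoods, normalised —
log space avoids underflow on 40-dimensional transfer features) is
cross-checked against the delegated backend to 1e-6. Prediction is the
argmax of class probabilities with ties broken toward the lower class
index.

## Synthetic data generator

The generator emulates the study conditions of the wearable benchmark the
scheme targets (no public accession exists, so nothing can be downloaded):

* **Templates.** Each class is one sinusoid per channel
  (amplitude·sin(2πft+φ)+baseline). This is deliberately the simplest
  model that yields class-separable periodic motion; difficulty is
  controlled by two knobs, the inter-template baseline gap and the noise
  sd. Frequencies span 0.4–1.8 Hz, the cadence band of slow therapy
  exercises.
* **Subjects.** 5 subjects; each contributes an additive per-channel
  offset drawn once (sd 0.3 in the reference spec), mimicking
  sensor-placement bias without modelling biomechanics.
* **Noise.** iid Gaussian per sample (sd 0.5 in the reference spec, giving
  a baseline-gap-to-noise ratio of 6 — comfortably separable, as the
  benchmark's near-ceiling accuracies suggest its classes are).
* **Class imbalance.** Proportions follow per-class row counts totalling
  276,625 with extremes pinned at 41,000 and 31,625 (the two published
  values). The six middle counts are not published; a straight linear
  interpolation between the extremes cannot reproduce the published total,
  so the middle counts are an evenly spaced decreasing sequence (mean
  34,000, step 750) constrained to the exact total. This is an assumption,
  documented here.
* **Apportionment.** Row counts per class use largest-remainder
  apportionment (floors plus top-up by fractional remainder, ties to the
  lower class index), so counts always sum exactly to the requested n; the
  same rule drives the stratified 80/20 split and reproduces
  221,300/55,325 at full scale.

What the generator does **not** emulate: biomechanically realistic limb
kinematics, orientation/quaternion dynamics, sensor drift, autocorrelated
noise, or within-class execution variability beyond subject offsets.
Passing tests on this data show the pipeline's mechanics (feature
construction, leakage control, evaluation arithmetic) are correct; they do
not certify accuracy levels on real recordings.

## Evaluation conventions

Per-class precision, recall, F1 and support are computed from the K×K
confusion matrix; zero-denominator cases yield 0 with a warning. Both
macro and support-weighted averages are reported; the weighted average is
the headline number for imbalanced classes. Display rounding is half-up at
2 decimals; machine-readable output keeps full precision. (The reference
tables' printed *F1* average cells are not reproducible from their own
rounded per-class cells — e.g. one table's cells average to 0.37 against a
printed 0.38 — so averages are always computed from unrounded internal
values; the printed *precision* averages, which do reproduce, are the ones
recomputed in the acceptance script.) Micro recall equals accuracy by
construction and is asserted as an identity. Cross-validation is
stratified k-fold (default k=10) reporting mean and sample (n−1) standard
deviation; with transfer features enabled, extractors are refitted inside
each fold on that fold's training part only. Stage runtimes are logged for
information and are never part of any comparison.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 1,200–2,000-row
tables, hidden sizes 8–32 and 2–10 training epochs — sizes at which every
stage's behaviour (separability, chance floor, leakage gap, determinism)
is already unambiguous. The full-scale (276,625-row) computations are
restricted to split arithmetic, which is exact at any scale. Degenerate
inputs are handled explicitly: empty tables read/write as header-only
files; test_fraction 0 yields an empty test partition; hidden size 0
disables the LSTM block (the transform degenerates to RF probabilities
exactly); epochs 0 leaves the initialised LSTM untouched but well-defined.

## Known limitations

* Out-of-fold LSTM features remain an approximation: hidden-state
  coordinates are only comparable across fold models because of the shared
  initialisation, not by any identifiability guarantee.
* The generator's sinusoid-plus-offset model makes classes separable from
  single rows; methods that exploit long-range temporal structure are not
  stress-tested by it.
* The reference benchmark itself is not redistributable here, so agreement
  with its published accuracy tables is checked only at the level of their
  internal arithmetic, not re-measured on the original recordings.
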