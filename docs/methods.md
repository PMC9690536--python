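# Methods

## Problem setting

Ordinal multi-instance learning (OMIL): a training sample is a bag
X_i = {x_i1, …, x_in} of instances with a single ordinal bag label
y_i ∈ {0, 1, 2} (normal < benign < cancer).  Instances carry hidden labels
y_ij ≤ y_i, and max_j y_ij = y_i — the bag's grade is the grade of its
strongest instance.  The learning goal is an instance-level scorer trained
from bag labels alone.

## Bag construction

Whole images are split on a `grid_rows × grid_cols` grid (default 14 × 7,
read as rows × columns because the images are taller than wide; 98
patches).  Non-divisible images are center-cropped first.  A patch is kept
when the fraction of its pixels above `foreground_threshold` (0.08) is at
least `min_foreground_fraction` (0.25); the thresholds are package
choices, selected so plain tissue passes easily while near-black border
patches fail.  Surviving patches are balanced to `target_bag_size` (70):

* surplus — keep the patches with the highest foreground fraction, ties
  to the lower row-major grid index, original order preserved (bright
  tissue is where lesions live, so dark patches are expendable);
* deficit — append augmented copies; the i-th copy applies transform
  `AUGMENTATIONS[(i // n) % 8]` (hflip, vflip, rot90, rot180, rot270, then
  hflip-composed rotations) to source patch `i % n`.  The rule is
  deterministic; copies inherit the source's grid position and hidden
  label.

Finally every patch is resized to `patch_side` (224) by bilinear
interpolation.  Filtering happens on native patches, before resizing.

## Scoring network

The instance scorer is a fixed small CNN: Conv 5×5×10 → ReLU → MaxPool 2
→ Conv 3×3×20 → ReLU → flatten (108·108·20 = 233,280) → FC 500 → ReLU →
head.  ReLU after FC1 follows standard practice.  The default head is a
single linear unit (scalar ordinal score); a 3-neuron softmax head serves
the cross-entropy baseline.  Parameter counts per layer are 260, 1820,
116,640,500 and 501 (1503 for the softmax head); closed-form calculators
for output sides and parameter counts double as test oracles against the
built network.

Initialization: `standard` draws weights from N(0, 2/fan_in) with zero
biases.  A literal all-zero initialization (`zero`) is retained
behind a flag; it is not trainable — with every weight zero, all ReLU
pre-activations vanish and so do all gradients — and exists only to make
that observation reproducible.

Inputs are intensities in [0, 1]; no mean/variance normalization.
Forward and backward passes are plain numpy (im2col convolutions,
channels-last); the Adam update over the 116.6M-parameter FC1 is
numba-compiled because it dominates step time otherwise.

## Losses and prediction

Prediction thresholds the scalar score at ordered cutpoints b1 < b2
(defaults 0.5 and 1.5 — midpoints between consecutive class indices,
i.e. classes are mapped to consecutive integers on the score axis).
Cutpoints are parameterised as (b1, δ) with b2 = b1 + softplus(δ), so
their order is structural.

Three per-instance losses are provided:

* `squared_error_ordinal` (default): L = (s − y)².  Selection then picks
  the instances whose scores sit closest to the bag's class index.
* `min_uncertainty_ordinal`: the all-threshold cumulative-logistic loss
  L(s, y) = Σ_c softplus(z_c (s − b_{c+1})), z_c = +1 if y ≤ c else −1,
  with trainable cutpoints updated by the same optimizer.  Analytic
  gradients w.r.t. s, b1 and δ are verified against finite differences.
* `cross_entropy`: −log p_y on the softmax head (probability floor 1e-12).

Why squared error is the default.  The all-threshold loss is one-sided
for the extreme classes: once a cancer-selected instance scores above b2
its gradient decays exponentially but never vanishes, and Adam's
per-parameter normalization turns those vanishing gradients into
full-size steps.  On cleanly separable synthetic data this drives the
top-class scores upward without bound (score means of 8–20 against a
fixed-width [b1, b2] middle zone in diagnostic runs), while the cutpoints
— two parameters moving at ~lr per step — cannot track the scale.
Feature-sharing then drags benign scores out of the middle zone and the
middle class collapses.  The squared-error form anchors every class to a
bounded target (its class index), which keeps the score scale matched to
the fixed prediction cutpoints and, empirically, lets benign-bag
selection find true benign instances (a virtuous circle the unbounded
form breaks).  The all-threshold loss remains available and fully tested
for users who want the cumulative-link form.

## Training loop

One bag per optimizer step: (1) forward all instances without gradient
bookkeeping and compute the loss vector against the bag label; (2) select
the k = 4 minimum-loss instances (ties to the lower index); (3) recompute
only the selected instances with intermediate caching and apply one Adam
step (lr 1e-4, decoupled weight decay 5e-4, eps 1e-6, betas (0.9, 0.99))
on the mean of their losses.  Bag order is reshuffled every epoch from
the run seed; selection carries no memory across visits.  Each step emits
a SelectionRecord (epoch E, selected indices and losses, the count S of
selected instances whose hidden grade equals the bag grade, and the
minimum unselected loss, which makes selection optimality checkable after
the fact).  Runs are bit-reproducible given (config, data, init).

The ordered binary decomposition baseline trains one scalar scorer per
class boundary c ∈ {0, 1} on relabelled bags (y > c vs y ≤ c) with a
logistic loss under the same key-instance mechanism; prediction counts
the scorers voting "greater".  In a two-class problem the logistic loss
and a two-class cross-entropy coincide, so the baseline contributes a
single row to the ablation grid.

## Evaluation

Instance-level evaluation fills a 3×3 confusion matrix from labeled ROI
patches.  Accuracy is the trace fraction; per-class accuracy is recall
per true class (undefined classes reported as NaN and excluded from macro
means).  Sensitivity, specificity, precision and F1 are computed under a
stated averaging mode: `macro_ovr` (unweighted one-vs-rest mean over the
three classes; default) or `disease_binary` ({benign, cancer} vs normal
with "diseased" positive).  F1 is the harmonic mean of the report's
aggregated precision and sensitivity.  Key-instance detection quality is
summarized per epoch over positive bags as mean S and selection precision
ΣS / (k · n_bags).  Selection montages outline correctly selected
instances in red, incorrect in blue, and in yellow when no hidden labels
exist.

## Synthetic data generator

Images are Gaussian-smoothed noise (mean 0.25, sd 0.05, smoothing σ 2.5)
with an optional near-black border of `border_margin` pixels.  Lesions
are radial blobs with a Gaussian intensity profile: grade 1 smooth and of
peak intensity 0.60, grade 2 spiculated (sinusoidal boundary perturbation,
amplitude 0.35, 5–9 spicules) with peak 0.90.  Each lesion is anchored
near the centre of its own interior grid cell (jitter ± cell/6), so a
blob corresponds to one clearly lesion-bearing instance — the discrete
structure the bag decomposition assumes.  Extra lesions beyond the forced
one take the bag grade with probability 0.7, otherwise a uniformly lower
grade.  A cell's hidden label is the maximum grade of any blob whose
support (distance ≤ effective radius) overlaps it by at least one pixel.
Generation is deterministic: each bag uses a counter-based substream of
the global seed, so datasets are reproducible independent of generation
order.

The default `border_margin` is 32 px — exactly one grid-cell ring at the
default geometry — so border cells fail the threshold filter outright
(98 → 60 survivors → 70 after augmentation).  A narrower margin leaves
edge cells half-bright; the filter then removes nothing and the
surplus-trim path could drop lesion cells, which would break the
strongest-label invariant.

The ROI test set (`make_instance_test_set`) cuts one cell-sized patch per
example: for positive classes, a lesion of the target grade is placed at
a cell centre and that cell is cropped (a clean, in-distribution example
of the grade); for class 0, an interior cell of a lesion-free image.

What the generator does not emulate: pectoral muscle, vessel structure,
acquisition artifacts, continuous lesion-grade ambiguity, annotation
noise, or the heavy class imbalance of screening populations.  Passing
tests on this data demonstrate that the selection mechanism and ordinal
losses behave as designed — not clinical-grade performance.

## Study scales

Two bundled presets (`oomil.presets`):

* `mammogram_scale` — 448 × 224 images, 14 × 7 grid, 70-instance bags of
  224 × 224, the full scoring network (116.6M parameters).  Used for the
  exact structural guarantees (patch counts, tiling, bag size,
  architecture table).
* `easy_study` — 192 × 96 images, 6 × 3 grid, 18-instance bags at 28 px,
  5–7 lesions per positive bag, 30 bags/class, 12 epochs, and the same
  network family at `input_side=28`.  A grid patch carries 32 × 32 pixels
  of information, so the reduced resolution discards nothing; the small
  variant trains in seconds per run on one CPU, which is what makes
  multi-seed training-dynamics tests practical.  Training-dynamics
  results (selection-precision trends, instance-level accuracy, loss
  ablations) are demonstrated at this scale.

## Numerical choices and degenerate inputs

float32 parameters and activations throughout; losses accumulated in
float64.  Ties in key-instance selection and in surplus trimming break to
the lower index (stable sort) for determinism.  Cross-entropy clamps
probabilities at 1e-12.  Empty bags after filtering raise a dedicated
`EmptyBagError`; k larger than the bag, mismatched head/loss pairs,
non-finite scores and invalid class indices raise ValueError.  Resize is
bilinear with output clipped to [0, 1]; a patch already at target size is
returned bit-identically.

## Known limitations

* The method needs positive bags to contain at least ~k instances of the
  bag grade for selection to avoid assigning the bag label to background;
  with rarer positives the middle class degrades first (the easy study is
  configured above that regime on purpose).
* Fixed-lr Adam without a schedule leaves converged runs mildly noisy;
  there is no early stopping or validation-based model selection by
  design.
* The full 224 px network is exercised structurally and through gradient
  checks but not trained to convergence in the test suite; its step time
  (seconds per bag on one CPU) makes full-scale training a
  compute-budget, not correctness, question.
* Bags are evaluated at instance level only; no bag-level test metric is
  defined (the ROI test set is the evaluation target).
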