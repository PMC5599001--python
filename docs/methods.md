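# Methods

## The model

`bactexture` treats species recognition in stained micrographs as
orderless texture classification.  An image is reduced to a set of
local descriptors, the set is pooled into a single vector whose
coordinates are sufficient statistics of the descriptor distribution,
and the vector is classified linearly.  The pooling step is the core:
it is invariant to where in the image structure occurs, which matches
the biology — what distinguishes a smear of chained cocci from one of
solitary rods is the *statistics* of local structure, not its layout.

### Dense SIFT

Descriptors are gradient-orientation histograms over a square patch of
side `4·bin_size` pixels: 4×4 spatial bins × 8 orientation bins =
128 components.  Gradients are central differences (one-sided at image
borders); each pixel's magnitude is split linearly between the two
orientation bins adjacent to its gradient angle and bilinearly between
adjacent spatial bins (triangular weights truncated to the patch
window, pixel offsets symmetrized by +0.5).  Descriptors are
L2-normalized, clamped at 0.2 and re-normalized — the standard
contrast-robust convention; flat patches return all-zero descriptors
rather than NaN.  Patches must lie entirely inside the image (margin
`2·bin_size`; no padding), and are sampled on a regular grid with step
2 px by default.  Defaults: `bin_size = 8`, single scale.  Only the
dense, upright, single-scale variant is implemented; keypoint
detection and rotation/scale invariance are out of scope.

The vectorized extraction is verified in the test suite against an
independent brute-force per-pixel/per-bin accumulation oracle to 1e-6.

### Deep descriptor backends

The same encoder accepts descriptor fields from a convolutional
backend (a network truncated at its last convolutional layer, giving a
W×H grid of D-dim vectors) and global vectors from a penultimate
fully-connected layer.  Pretrained ImageNet networks (AlexNet "AN",
VGG-M "M", VGG-VD "VD") are adapter slots that raise a clear
"backend not available" error unless the user supplies weights; they
are never silently substituted.  A seeded toy backend (8 zero-mean
random 3×3 filters, rectification, stride 4; FC vector = per-channel
global mean and max on a 64×64 resize) ships so the FV-CNN / FC-CNN
code paths are exercised end to end without weights.  It is a plumbing
test vehicle, not a trained feature extractor.

### Fisher-vector encoding

A diagonal-covariance GMM with K components is fitted to descriptors
pooled from the *training* images of each split (never test images).
Fitting is EM from a k-means initialization (seeded), with:

- log-domain responsibilities (log-sum-exp), so no underflow;
- variance floor `1e-4 ×` per-dimension data variance;
- stop when relative log-likelihood improvement < 1e-6 or at 200
  iterations; the per-iteration log-likelihood trace is retained on the
  model (it is non-decreasing up to round-off — checked for 50 seeded
  fits in the tests);
- a component whose responsibility mass collapses below 1e-8 is
  re-seeded once at a random data point; a second collapse is an error.

Before the GMM, SIFT descriptors are optionally PCA-projected
(decorrelation supports the diagonal-covariance assumption and cuts
cost); deep descriptor fields skip PCA by default.  The GMM is fitted
on a seeded subsample of pooled descriptors (default cap 100 000).

Encoding computes, per component k, the soft-assignment-weighted
first-order and second-order statistics

    Φ¹ₖ = 1/(N√wₖ)   Σᵢ γᵢₖ (xᵢ−μₖ)/σₖ
    Φ²ₖ = 1/(N√(2wₖ)) Σᵢ γᵢₖ ((xᵢ−μₖ)²/σₖ² − 1)

concatenated as all first-order blocks then all second-order blocks
(components ascending), length 2·K·d.  Zeroth-order (mixture-weight)
statistics are excluded.  Responsibilities below 1e-8 are truncated to
zero for speed (configurable off).  Normalization is signed square
root followed by global L2 (`ssr+l2`, the improved-FV convention);
`ssr` and `off` are available.  The encoder is validated against a
naive per-descriptor double loop (1e-8) and against the property that
descriptors sampled from the fitted model itself have expected score
zero.

Defaults: K = 64, PCA dim 64 for SIFT.  The bundled synthetic study
uses K = 32, PCA dim 48 and a 20 000-descriptor subsample — at 100–240
images of 96–128 px these values saturate accuracy while keeping a
full repeated run in minutes on one CPU.

### Representations and recipes

Part tags follow the encoder–descriptor naming scheme: `FV-SIFT`,
`FV-<backend>`, `FC-<backend>`, and `FCFV-<backend>` as shorthand for
FC + FV of one backend; parts are combined with `&`.  Each part is
L2-normalized independently, concatenated, then globally L2-normalized,
so no part dominates by scale alone.

### Classifiers

- **original** — one-vs-all linear SVM, C = 1; prediction is the argmax
  of per-class decision values, ties toward the lowest class id.
- **linear / poly / rbf** — one-vs-one SVMs whose hyperparameters
  (log₁₀C ∈ [−3, 3]; log₁₀γ ∈ [−4, 1] for RBF; degree ∈ {2, 3, 4} for
  polynomial) are tuned by Bayesian optimization: a Matérn-5/2 GP
  surrogate with expected-improvement acquisition over seeded random
  candidates, 25 evaluations by default, objective = mean 5-fold
  stratified CV accuracy on the training set; the winner is refitted on
  all training data and the full trace is stored.  The optimizer is
  implemented in-package on scikit-learn's Gaussian-process regressor.
- **rf-adaboost** — multiclass AdaBoost (SAMME) over depth-limited
  trees; estimator count ([50, 300]) and depth ({1, 2, 3}) tuned under
  the same protocol.  The name records the ensemble family this slot
  represents; boosting is the algorithm actually run.

All classifiers standardize features to training-set mean/variance
internally and carry the scaler in their fitted state.  Class ids of
the form "major.minor" order numerically (2.1 < 10.2 < 10.10), which
fixes tie-breaking and report ordering.

## Evaluation protocols

**Repeated equal splits.**  Each class contributes `per_class_train`
training and equally many test images (default 10/10), drawn without
replacement with a per-class sub-seed (`master seed + class position`,
so adding a class never perturbs others' splits).  Each repeat r uses
split seed `seed + 1000·r`, refits PCA + GMM on its training half only,
trains the classifier and scores the test half.  Reported: per-repeat
accuracies (micro-average fraction correct), mean ± std in percent,
per-class accuracy (confusion diagonal / row sum), and the confusion
matrix accumulated over repeats with entry (i, j) = observations of
true class i predicted j.  Dense-SIFT fields are cached per image
across repeats (descriptors don't depend on the split); everything
split-dependent is refitted.

**Scalability.**  For each subset size n and repeat, a seeded random
n-class subset is drawn, and one full split/fit/score cycle is run with
the one-vs-all linear SVM (C = 1).  Accuracy (percent) is regressed on
n by ordinary least squares, one line per repeat; the extrapolated
accuracy at a target class count (default 100) is reported as the mean
of per-repeat predictions ± their standard deviation.  The ± is thus a
repeat-to-repeat dispersion, not a standard error of the pooled fit;
the pooled-fit slope and intercept are reported alongside.  This
definition is one of several defensible ones and is fixed here for
reproducibility.

## Synthetic textures

The generator emulates the morphotype axes along which stained smears
differ: particle shape (disc, rod, curved rod — arcs subtending 1.8
rad), size (Gaussian-jittered), density (expected particles per 10⁴
px², Poisson count), and arrangement (solitary; chains placed along a
direction-jittered path with consecutive cells touching, each cell
aligned to the local chain direction; clusters dispersed isotropically
around an anchor).  Particles render as anti-aliased capsules at a
bright foreground intensity on a dark background (overlaps combine by
intensity max, as overlapping translucent cells roughly do), plus
clipped additive Gaussian noise.  Everything derives from one seed;
identical spec + seed is bit-identical.

What it does **not** model: staining color (the pipeline is
grayscale), focus and illumination gradients, debris and artifacts,
cell-size correlation within a field, biologically realistic colony
growth.  Passing tests on these textures therefore demonstrate that
the pipeline's machinery (descriptors, encoding, classification,
evaluation accounting) works and that morphotype-style texture
contrasts are recoverable — not that any particular accuracy carries
over to real micrographs.

Two presets are frozen in code: `demo5` (5 well-contrasted classes:
solitary discs, clustered discs, solitary rods, chained rods, curved
rods) and `scale12` (3 shapes × 3 arrangements + 3 size/density
variants) for the scalability ladder.  The study sizes are 20
images/class at 128 px (`demo5`) and 96 px (`scale12`), chosen so a
full repeated run stays in the minutes range on a single CPU while
each image still yields ~1000–2400 descriptors.

## Numerical and design choices

- Grayscale conversion by ITU-R 601 luminance weights; the descriptors
  are gradient-based, so color is deliberately ignored (a color
  extension would be a separate representation part).
- Optional downscale of loaded images to a 512-px longest side
  (bilinear, aspect preserved).
- Coordinates are 0-based, row-major (row, col).
- Accuracy is the micro-averaged fraction of correct test images;
  per-class accuracy is reported separately rather than macro-averaged
  into the headline number.
- All stochastic stages (generation, splits, subsampling, k-means/EM,
  toy filters, Bayesian optimization) consume seeds derived from one
  master seed; machine-readable outputs of a seeded run are
  byte-identical across reruns.
- Degenerate inputs: flat patches → zero descriptors; empty descriptor
  sets, single-class training sets, undersized classes and dimension
  mismatches raise informative errors rather than propagating NaNs.

## Known limitations

- The toy backend's features are weak by construction; FV-CNN/FC-CNN
  accuracy with it is not indicative of pretrained-network accuracy.
- The linear extrapolation of subset accuracy is descriptive: on the
  12 synthetic classes the accuracy-vs-n slope is far steeper than one
  would expect across real species, because synthetic classes are
  built from a handful of morphotype axes and become confusable
  quickly; extrapolations to 100 classes from such a ladder can leave
  [0, 100] entirely and should be read as a trend summary only.
- Multi-scale dense SIFT, VLAD/bag-of-words alternatives, probability
  calibration and significance testing between methods are not
  implemented.
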