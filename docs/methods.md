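# Methods

## Mutual-information estimation

All information quantities are plug-in (maximum-likelihood) estimates from
discretized joint histograms, in **bits** (log base 2). Bits were chosen for
interpretability; the base is a global scale factor and cancels in every
argmax decision the selector makes. No small-sample bias correction is
applied: the plug-in estimator is biased upward at small n, but the bias is
shared across candidates compared at the same n and subset size, so it does
not change selection order in practice; absolute relevance values should not
be read as unbiased information estimates.

Continuous columns are discretized before estimation. The default is
**equal-frequency binning with 10 bins**: quantile-based bins are robust to
the heavy-tailed, spike-at-zero marginals typical of deep-network activation
features, whereas equal-width bins can collapse most mass into one bin.
Equal-width is available via configuration. Duplicate quantile edges are
merged, so a column takes at most 10 distinct codes and a constant column
collapses to a single category without error. Integer class labels are used
as-is, never re-binned.

Numerical conventions: entropies and MI are accumulated with exactly rounded
summation (`math.fsum`) and marginals are computed by direct counting rather
than axis sums of the joint table, which makes I(x;y) = I(y;x) and the
lazily-cached pairwise matrix bit-for-bit reproducible regardless of
evaluation order. Tiny negative MI from rounding is clamped to exactly 0.

## The mRMR selector

Relevance of a subset is the mean MI of its members with the label;
redundancy is the mean over **all ordered pairs including i = j** of the
pairwise MI (the diagonal contributes each member's entropy). The literal
|S|² normalization is used for the reported D, R, Φ trace; the greedy
selection itself uses only the incremental criterion
J(x_j) = I(x_j;c) − (1/|S|) Σ_{x_i∈S} I(x_i;x_j), so the diagonal convention
affects reporting, not which features are chosen.

Greedy ties at the argmax resolve to the lowest feature index. Scores within
1e−9 of the running maximum are treated as tied: mathematically equal scores
computed along different floating-point paths can differ in the last bit,
and without the guard the tie-break would be decided by rounding noise.
Genuinely distinct MI values on continuous data differ by far more than the
guard.

Pairwise MI values are computed lazily and memoized, so a run that stops
after K features touches only O(K·m) of the m² pairwise entries.

### Stopping rule

After each addition the stratified k-fold (default 10) CV accuracy of the
current subset is compared with that of the subset without its newest
member. Both are evaluated on the **same fold partition** (derived once from
the seed), so the comparison is paired rather than confounded by fold
resampling noise. "Reduced" is read as a strict decrease by default; a
non-strict mode (ties also stop) is available. Fold accuracies are averaged
unweighted — folds differ by at most one instance.

The stopping classifier defaults to Gaussian naive Bayes (scikit-learn's
`GaussianNB`); the contract accepts any object with `fit`/`predict`, so an
SVM or any other scikit-learn classifier can be substituted. Naive Bayes was
chosen as the default because it is fast enough to be re-fit k times per
selection step and has no tuning parameters that would interact with the
stopping signal.

Folds are built per class: each class's instances are shuffled (seeded) and
dealt round-robin across folds, with the starting fold rotating between
classes to balance total fold sizes. This supports k up to n (singleton
folds) even when a class has fewer than k members, which off-the-shelf
stratified splitters reject.

## Evaluation metrics

Binary confusion metrics follow the standard definitions (see README). A
zero denominator (for example PR with no positive predictions) yields an
explicit `None` marker instead of a silently coerced 0 or 1, which would
bias comparisons between classifiers. Multi-class problems are reduced to
one-vs-rest counts per class plus an unweighted macro average; the metric
definitions themselves are binary. The holdout protocol is a stratified
70/30 split by default.

## Image preprocessing

The chain is: Otsu binarization → erosion → median filtering of the
grayscale image with re-thresholding of the refined mask → dilation →
retention of the largest 8-connected components → flood-filling of interior
holes. Masked output keeps source intensities inside the mask and is 0
outside.

Conventions (configurable): structuring elements are (2r+1)×(2r+1) squares
with r = 1 by default; out-of-bounds neighbors count as background for both
erosion and dilation, so masks shrink at the border under erosion; the
median filter uses a 3×3 window with edge-inclusive reflected padding;
connected components use 8-connectivity, flood fill uses 4-connectivity for
the background; `keep_components` defaults to 2, matching the two lung
fields of a chest image. Contours are ordered closed pixel paths traced with
Moore-neighbor tracing (clockwise, starting at the topmost-leftmost pixel);
a filled n×n square yields the expected 4(n−1) boundary pixels. Coordinates
are 0-based, row-major, origin top-left; grid extents are half-open. A
constant image has no Otsu threshold and falls back to the fixed midpoint
127.5 with a warning; an empty final ROI is returned with a warning rather
than raised.

Erosion before dilation forms an opening, which removes speckle foreground
smaller than the structuring element; re-thresholding the median-filtered
image and intersecting suppresses noise-flipped pixels before the mask is
re-expanded.

## Synthetic benchmarks

`generate_table` plants three kinds of columns: *relevant* columns are
class-conditional Gaussians with unit variance and class means separated by
`effect_size` (default 1.5 standard deviations — a strong but not trivial
signal, giving single-feature CV accuracy around 0.77 at the default n);
*copies* are ρ·parent + √(1−ρ²)·ε with ρ = 0.95 by default, i.e. almost
interchangeable with their parent for classification; *noise* columns are
standard normal and label-independent. Defaults (n = 1000 instances,
5 relevant, 1 copy each, 40 noise, 2 balanced classes) define the benchmark
family used throughout the tests and the acceptance script. What this
emulates is the qualitative structure of a deep-feature table — informative
dimensions, near-duplicates, dead units. What it does not emulate: real
activation marginals (non-Gaussian, sparse), correlated noise between
"irrelevant" features, and label noise; passing the planted-recovery tests
therefore demonstrates correctness of the selection machinery, not expected
accuracy on any real imaging dataset.

`generate_phantom` renders a dark background (level 20), two bright
elliptical "lung" fields (level 130, semi-axes 0.34/0.15 of the 640-pixel
side), and brighter circular "nodules" (level 230) constrained to lie inside
the ellipses, with additive Gaussian pixel noise (σ = 8 by default) clipped
to [0, 255]. Ground-truth ROI and nodule masks are exact by construction.
The intensity polarity is simplified relative to real CT (where aerated lung
is dark inside a bright body); the phantom exercises the morphological
chain, not radiological realism.

All randomness flows from one integer seed per artifact through
`numpy.random.default_rng`, so every fixture is reproducible.

## Problem sizes

The acceptance script uses 100 seeded replicates for the selector rates and
50 for the phantom segmentation rate, matching the benchmark family's test
conditions, and completes in roughly half a minute on one CPU; the oracle-
equivalence suite runs 50 random tables with n ≤ 60 and m ≤ 15, where the
naive reference selector (which re-estimates every MI from raw data at every
step) is affordable.

## Known limitations

- The plug-in MI estimator with fixed binning is inconsistent for truly
  continuous dependence structures at small n; k-NN (Kraskov-type) and
  Bayesian estimators are out of scope.
- The stopping rule compares noisy CV estimates; with a weak signal it can
  stop one step early or late. The paired-fold design reduces but does not
  eliminate this.
- Multi-label targets, other selector families (ReliefF, LASSO, wrappers),
  ROC/AUC evaluation, and any network feature extraction are out of scope.
- Images enter as 8-bit grayscale PNG/BMP; DICOM is out of scope.
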