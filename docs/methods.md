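# Methods

This note documents the procedures implemented in patchflow, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic cohorts do and do not emulate, and the numerical choices made
where a design was genuinely open.

## Scope and model of the problem

patchflow implements the *pipeline* half of a medical-imaging
experiment: everything between raw files on disk and a metrics table,
with the predictive model abstracted behind a fit/predict contract
(`ModelContract`). The package assumes:

* images are dense intensity grids with 2 or 3 spatial axes, a leading
  explicit channel axis, per-axis physical spacing, and an origin;
  orientation (direction cosines) is deliberately out of scope — axes
  are taken as stored, and only spacing and origin survive resampling;
* label maps are non-negative integer grids aligned to their image's
  spatial shape, with 0 reserved for background everywhere;
* a cohort is a set of uniquely identified subjects, each with one or
  more image channels and exactly one target (mask path, class index,
  or scalar);
* models are deterministic given their seed, and segmentation models
  emit per-pixel class probabilities that sum to one.

## Harmonization

All intensity steps run channel by channel. Channels represent distinct
modalities (e.g. different MRI sequences) whose intensity scales are not
comparable, so pooling statistics across channels is never correct by
default; this per-channel convention is a deliberate design choice, not
an inference about how any particular study pooled its statistics.

* **Band thresholding** zeroes values outside `[min, max]`;
  **clipping** clamps them to the band (CT windowing). Both are exact
  elementwise rules and are tested against brute-force loops.
* **Z-score normalization** uses the population (divide-by-n) standard
  deviation — deterministic and the common imaging convention. The
  `nonzero_only` variant computes statistics over voxels with |x| > 0
  and resets originally-zero voxels to exactly 0 afterwards, so
  skull-stripped backgrounds stay aligned with their masks.
* **Resampling** uses order-1 (linear) interpolation only: it is
  monotone, so no overshoot appears near label edges; label maps always
  use nearest-neighbour and therefore can never acquire a label absent
  from the input. Output grids are defined on pixel centers
  (`grid_mode` resampling); physical extent is preserved to within one
  voxel per axis. Cubic interpolation is intentionally not offered.
* **Global histogram equalization** maps each value to the empirical
  CDF of its histogram bin (default 256 bins), yielding a monotone map
  onto [0, 1].
* **Augmentations** are the simple family: axis flip, 90° rotation
  (applied identically to image and label), additive Gaussian noise and
  Gaussian blur (image only). The experiment runner honours per-entry
  probabilities with one seeded uniform draw per transform per sample.

## Nested cross-validation and penalties

Subject ids are shuffled once with a seeded generator and assigned to
outer folds contiguously in shuffled order; `numpy.array_split`
semantics give fold sizes differing by at most one, with earlier folds
taking the extra subject. Inner folds partition each outer remainder
the same way. `k_outer = 1` means no held-out test set; symmetrically,
`k_inner = 1` means no held-out validation set (the full remainder
trains). The minimum cohort size is `k_outer × k_inner` so no partition
is empty. The validation fraction is defined as a fraction of the
*remainder*, not of the full cohort — with 5×5 nesting of 100 subjects
this gives the 20/16/64 test/validation/train layout and 25 trained
models.

Penalty weights are `p_c = 1 − n_c/N` computed from the **training
partition only** of each fold (counting cases for classification,
voxels for segmentation). A zero-count class gets weight 1 exactly, with
no re-normalization; an explicit penalty map in the config overrides
the automatic computation for such cases.

## Patch mining and tissue masking

The pseudo-grid places start coordinates at stride
`max(1, ⌊size·(1−overlap)⌋)` per axis and appends a final coordinate
clamped so the last window ends exactly at the axis length: every pixel
is covered, no window exceeds the image, and no padding is ever needed.
The stride floor of 1 keeps the grid finite as overlap approaches 1.

The tissue mask combines two background rules on the [0, 1]-rescaled
image at a coarse downsample level: (i) all three channels above a
white cutoff (default 0.9), and (ii) grayscale value — the mean of R,
G, B — above the Otsu threshold of the grayscale histogram. Tissue is
the complement. The exact combination rule of the white-cutoff and Otsu
components is this package's own choice (the simplest conjunction that
removes both bright slide background and pale smudges); other RGB rules
are conceivable. Patch coordinates are stored at full resolution and
mapped onto the coarse mask by integer division; partially covered mask
pixels at window edges count as background, which is conservative.

Otsu's threshold is computed on an `n_bins` histogram by maximizing the
between-class variance over all interior bin edges. When the histogram
has an empty gap between modes, several adjacent split points are
exactly tied; the implementation returns the first maximizer, and the
tests accept any threshold achieving the maximal variance.

## Stitching and inference

The stitch accumulator stores integer contribution counts and divides
the prediction sum once at the end — one rounding site, and the result
is algebraically identical to multiplying the summed probability map by
a reciprocal count map. This normalization is what keeps stitched
probabilities in [0, 1] regardless of overlap. Uncovered pixels carry
probability 1 for the background class (id 0 by convention everywhere).

Crop-mode stitching trims `⌊overlap·size/2⌋` per interior side of each
patch; sides touching the image border keep their full extent so edges
stay covered, and the first patch claiming a pixel keeps it, making the
result independent of patch order.

Slide inference chains tissue mask → pseudo-grid → tissue-fraction
filtering → per-patch prediction → average-mode stitch → per-pixel
argmax on tissue pixels (background elsewhere). An empty tissue mask
produces a warning and an all-background output, not an exception.

Fold-ensemble fusion uses per-pixel majority vote for segmentation,
majority vote over predicted classes for classification, and the
arithmetic mean for regression; all ties break toward the smallest
class id. Majority voting was chosen as the minimal member of the
label-fusion family; probabilistic fusion (e.g. STAPLE) is out of
scope.

## Metrics

* **Dice** of two empty sets is defined as 1.0 (perfect agreement on
  absence); empty on one side only gives 0.0. This matches the dominant
  segmentation-challenge convention.
* **HD95** extracts boundaries by face-connectivity erosion (4-/6-
  neighbourhood), computes exact Euclidean distances between boundary
  point sets via a spacing-aware distance transform, takes the 95th
  percentile of each directed distance multiset with linear
  interpolation between order statistics, and returns the larger of the
  two. An empty class on either side yields NaN — reported as missing,
  never as 0.
* **Balanced accuracy** is the mean of sensitivity and specificity; the
  multiclass form is the macro-average of per-class recall, which
  reduces exactly to the binary formula for two classes. Undefined
  denominators yield NaN.

## Synthetic cohorts and reference models

The 3D generator emulates multi-channel radiology volumes: one
ellipsoidal blob per foreground class over a zero background, class `c`
at mean intensity `c·Δ` with `Δ = 10 · noise_std` (1.0 when noiseless),
plus i.i.d. Gaussian noise. The 2D generator emulates a flat stained
slide: near-white background (values ≥ 0.95), pink tissue disks, purple
lesion disks strictly inside tissue occupying approximately a requested
fraction of the tissue area. Each subject's stream derives from
`(seed, subject_index)`, so cohorts are pure functions of their spec
and carry no cross-subject correlation.

The ten-standard-deviation class separation is deliberate: it makes the
classes essentially perfectly separable, so an end-to-end test that
fails is diagnosing pipeline plumbing, not model capacity. The flip
side is what these cohorts do **not** emulate: partial-volume effects,
intensity non-uniformity, anatomical shape variation, stain variation,
scanner differences, or annotation noise. Passing tests demonstrate
that the machinery is correct, not that any model generalizes to
clinical data.

Reference models are single-shot and deterministic: a
nearest-class-mean segmenter fitted on training labels, a
training-mean regressor, a training-majority classifier, and a
test-only oracle segmenter with known class signatures. "Epoch"
statistics reduce to one fit per fold for these models; iterative
plug-ins define their own epoch granularity behind the same contract.

## Experiment runner

All randomness flows from the single config seed through named
substreams (`SeedSequence([seed, outer, inner])` per fold), so results
are independent of fold execution order and repeated runs are
byte-identical. Train/validation/test disjointness is asserted at
runtime inside every fold. A fold failure is logged and the remaining
folds proceed; completed fold outputs are never lost, and an error is
raised only after everything has been written. Fitted reference models
serialize to small JSON artifacts, which also makes the inference-side
ensemble reproducible and auditable.

Default config values: overlap 0, average stitching, automatic
penalties, seed 42, background-plus-one-foreground class list, current
package version recorded in every model artifact. Unknown config keys
are rejected with a closest-match suggestion rather than silently
ignored.

## Problem sizes used in the automated checks

The test suite runs the full 5×5 nested loop on a 25-subject noiseless
cohort of 32³ volumes (the smallest size at which the 20/16/64
arithmetic is exact and every fold sees several blobs), the slide path
on a 1024×1024 pseudo-WSI with 128² patches at 25% overlap, and the
oracle-equivalence checks on 100 random histograms, 50 random 16×16
mask pairs, and randomized patch sets. These sizes were chosen as the
smallest at which each property is non-trivially exercised.

## Known limitations

No DICOM or pyramidal slide containers; no affine reorientation; no 4D
series. No stratified or grouped splitting beyond the subject level.
No gradient-based training, loss functions, or GPU execution — the
penalty weights are computed and handed to the model contract, and what
a model does with them is its own affair. Morphological duality between
dilation and erosion holds exactly only away from the image border
(the border is treated as background).
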