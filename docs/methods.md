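# Methods

`celltax` implements an image-based cell-line authentication workflow:
brightfield micrographs of cultured cells are segmented into single-cell
patches, patch classifiers are trained over a factorial grid of transfer-
learning design choices, the resulting models are combined by soft voting,
and design choices are compared with paired nonparametric statistics.
Because real microscope datasets of this kind are typically distributed on
request only, the package ships a synthetic scene generator with exact
per-cell ground truth so that every stage is runnable and testable on a
laptop CPU.

## Synthetic brightfield scenes

A scene is a bright, noisy field (default background intensity 200, white
Gaussian sensor noise with sd 2) containing non-overlapping elliptical cell
bodies and small floating debris.  Each of the four classes is a morphology
template with six parameters: major-axis diameter (mean/sd, pixels),
eccentricity range, rim darkness (intensity drop of the dark contour that
brightfield optics produce at the cell boundary), interior texture
amplitude and texture correlation length.  Cells are rendered as rotated
ellipses: a uniform interior attenuation (22 intensity units), a ~3 px dark
rim, and a low-frequency Gaussian texture field confined to the interior
(the rim stays uniformly dark, as texture is a cytoplasmic property and a
broken rim would be an optical artefact).

The default templates (diameters 56/66/76/86 +- 3 px; eccentricities
0.2-0.5; rim depths 60/35/80/25; texture amplitudes 8/22/14/30 at scales
9/5/13/4 px) are synthetic plumbing, not models of any real cell line.
They were chosen once to satisfy three structural requirements:

* every rendered cell's tight box satisfies `w + h >= 100` px and every
  debris speck's box satisfies `w + h < 100` px, so the segmentation size
  filter is exact by construction;
* scene-level mean box diameter separates the classes cleanly (class gaps
  of ~8-10 px against scene-level sds of ~1 px), guaranteeing learnable
  signal downstream;
* 8-16 cells pack into a 640x480 scene without overlap.  Placement is
  rejection sampling with a 4 px guard margin and at most 100 retries per
  cell; an infeasibly dense specification raises `OvercrowdedSceneError`.
  (A wider default range was considered and rejected: above ~18 of the
  largest cells, random sequential packing of non-overlapping ellipses at
  the size the `w + h >= 100` filter forces cannot fill a 640x480 frame.)

Every output is a pure function of the specification and a seed; per-image
seeds in a dataset derive deterministically from the master seed.

What the generator does **not** emulate: confluent sheets and touching
cells, mixed-class flasks, illumination gradients, defocus, chromatic
content (channels are identical), and real within-line morphological
heterogeneity.  Tests passing on these scenes therefore validate the
pipeline's mechanics and relative orderings, not absolute accuracy on real
micrographs.

## Segmentation

The chain mirrors standard brightfield practice: BT.601 luma grayscale
conversion; adaptive thresholding in which a pixel is foreground when it is
darker than its 51x51 local mean by more than 5 intensity units (cells are
dark on a bright field); one dilation with a 2x2 kernel to consolidate
fragmented contours; tight bounding boxes over 8-connected components;
a size filter retaining boxes with `w + h >= 100`; and colour crops from
the original image.  The local-mean operator, window 51, offset 5, one
dilation iteration, 0-based half-open box coordinates, keeping nested and
border-touching boxes — all are explicit package defaults exposed in
`SegmentationParams`.  On 50 default scenes the recovered boxes match
ground-truth cells with precision and recall 1.0 at IoU >= 0.5, and no
debris box survives the filter.

## Patch preparation

Patches are resized (bilinear, aspect-destroying) to each architecture's
input size and normalized by that architecture's published convention:
scale to [0,1] then ImageNet channel standardization (DenseNet121); BGR
swap plus ImageNet mean subtraction on the 0-255 scale (ResNet50); [-1,1]
scaling (MobileNetV2, InceptionV3); [0,1] scaling (EfficientNetB2).  All
modes are per-channel affine maps.

Augmentation draws a rotation uniform in [0, 90] degrees, integer
translations in [-2, +2] px per axis, and a vertical flip with probability
0.5, filling exposed borders by edge replication.  It is applied on the
fly each epoch, and — deliberately — to the *original* crop before the
network resize: augmenting after downsampling low-passes the training
stream but not the test stream, and that train/test mismatch measurably
cancels the benefit of augmentation at small scale.

## Models and the training grid

Five published backbones (DenseNet121, MobileNetV2, EfficientNetB2,
InceptionV3, ResNet50) are represented by exact layer-level parameter
tables: every convolution and batch-normalization with its trainable and
non-trainable tensor sizes, in network order.  With the global-average-
pooling + 4-way-softmax head (feature_dim x 4 + 4 parameters, always
trainable) these tables give the trainable counts under both fine-tuning
regimes.  "Freeze the first 25% of layers" is framework-enumeration-
dependent, so the boundary is a recorded per-architecture constant; each
recorded boundary falls on a published block edge (e.g. stem + conv2 stage
for ResNet50, stem + first inception block for InceptionV3).  Pretrained
weights are not shipped and the canonical backbones are accounting-only
handles.

Trainable end-to-end runs use the smoke family: five small
conv-BN-ReLU-pool x2 + GAP + dense(4) networks (widths 8/16 through
16/32, 32 px inputs), one per normalization mode, sharing every contract
(freeze policy, optimizers, schedule, simplex outputs) with the canonical
specs.  Batch normalization is included for the same reason the published
backbones use it: without it, training at the study's fixed 0.001 learning
rate is impractically slow.

The design grid crosses four binary choices — augmentation on/off; all
weights trainable vs. first quarter frozen; SGD (momentum 0) vs. AdaGrad
(eps 1e-7, zero initial accumulator); fixed 0.001 learning rate vs.
continuous exponential decay `eta(t) = 0.001 * 0.96**(t / 10000)` — for 16
configurations per architecture, trained with categorical cross-entropy
under five-fold cross-validation.  Folds partition source images, not
patches, stratified by class: patches from one micrograph are correlated,
and image-level splitting is the leakage-safe choice.  Per-fold seeds
derive from (master seed, architecture, configuration index, fold), so any
grid cell is reproducible in isolation; `run_grid` persists each record as
JSON and resumes interrupted sweeps.

Default batch size is 32.  The smoke profile (8 images per class, ~450
patches, 5 epochs) uses batch size 8: with ~360 training patches per fold,
batches of 32 would yield only ~60 gradient steps over a whole run, too
few for any learning at the fixed 0.001 rate; batch 8 keeps the
step-count-to-data ratio in a sensible regime while remaining a standard
choice for datasets of this size.

## Ensembles

Records are ranked by mean cross-validated accuracy (ties broken by
canonical configuration order).  Single-architecture ensembles take the
top-4/8/16 configurations of one backbone (15 pipelines across five
backbones); multi-architecture ensembles take the top-1/2/3 per
architecture (5/10/15 members).  Prediction is soft voting: element-wise
sum of member probability rows, argmax per sample, ties toward the lowest
class index.  Sum and mean aggregation are order-equivalent, so duplicating
members never changes predictions.  Selection and evaluation use the same
cross-validation metrics; that reproduces the study protocol as specified
but is optimistic relative to selection on a held-out split — a caveat for
any absolute reading of ensemble accuracies.

## Metrics and statistics

Accuracy, precision, recall and F1 are reported in percent with
support-weighted multiclass averaging, under which weighted recall equals
accuracy identically (scikit-learn computes the tallies behind the
`MetricsReport` surface).  Paired comparisons use a two-sided Wilcoxon
signed-rank test with the statistic `W = min(W+, W-)`: zero differences
dropped, tied absolute differences mid-ranked, exact null distribution for
n <= 25 pairs (a dynamic program over doubled ranks, which are integers
even with mid-rank ties — a case scipy's exact mode does not support),
normal approximation with tie and continuity corrections above.  Stars
follow the usual convention (* p<0.05, ** p<0.01, *** p<0.001).  Factor
comparisons pair the 8 configurations at one factor level with the 8
matched configurations at the other level and test over fold-level
accuracies (40 pairs for a full grid); the pairing unit is a package
decision, as is the two-sided alternative.  No multiple-testing correction
is applied.

## Baselines

The classic-ML arm grayscales each patch, resizes it to 64x64, and
extracts a HOG descriptor (9 orientation bins, 8x8 px cells, 2x2-cell
blocks, L2 block normalization with clipping; 1764 features), classified
with an RBF SVM (C=1), a 100-tree random forest, LDA, and 5-NN — standard
defaults, all exposed in `HogParams` and the classifier factory.  The arm
consumes the identical image-level folds as the network grid so that the
two arms form valid pairs.

## Scales used by the shipped checks

The test suite and the acceptance script run entirely on synthetic data at
CPU scale: 50 scenes for the segmentation property suite, and a smoke
study of 8 images per class (~450 patches), a 4-configuration sub-grid on
the smallest architecture, 5 epochs, batch 8, five-fold CV; the ensemble
property repeats a 5-member heterogeneous ensemble across five seeds.
These sizes are the package's own reproducibility-oriented defaults; the
full 5-architecture x 16-configuration x 50-epoch sweep is expressible
with the same API (`run_grid`, `run_pipeline`) given proportionally more
compute.

Two smoke-scale caveats deserve stating plainly.  First, the augmentation
effect at 5 epochs on ~450 patches is small and seed-dependent: positive
in most runs (a few percentage points), negative in others; only the
ensemble-over-member-mean ordering is consistently reproduced across
seeds.  Second, on these clean synthetic scenes the HOG + classic-ML
baselines are very strong (rim contrast and texture are exactly what HOG
measures) while the 5-epoch CNNs are deliberately undertrained, so the
full-scale ordering "networks beat hand-crafted features" does NOT hold at
smoke scale and the test suite does not assert it.  Neither caveat says
anything about real micrographs; both are properties of the scaled-down
regime.

## Known limitations

* Canonical backbones are parameter-accounting handles; no pretrained
  weights, no canonical-backbone training in-package.
* The generator's simplifications (isolated cells, identical channels, no
  illumination field) make segmentation easier than on real data; the
  perfect precision/recall on synthetic scenes is an upper bound.
* Ensemble member selection on CV metrics is optimistic (see above).
* The numpy engine is single-threaded and deliberately minimal (3x3
  convolutions, 2x2 pooling); it targets correctness and determinism, not
  throughput.
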