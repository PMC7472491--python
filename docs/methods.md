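# Methods

## The measurement model

A standing subject on a 48×48 pressure mat (400 mm × 400 mm, so one cell ≈
8.33 mm) produces one frame per foot in kPa.  The device also exports an
interpolated 918×918 color image of the pressure distribution;
`grid_to_image` emulates that export with a blue→green→red colormap over a
white background, nearest-neighbor upsampled by default (cell boundaries
preserved; bilinear available).  The colormap is piecewise linear through
blue–cyan–green–yellow–red, so on the half-degree HSV convention (H 0–180,
S/V 0–255) the whole footprint occupies H 0–120 with S ≥ 30 separating it
from the white background, and the highest-pressure band renders in
H 0–40 — the two color ranges the preprocessing chain keys on.

## Arch index

The arch index is the midfoot share of toe-less contact area,
AI = B/(A+B+C).  Choices that the classic definition leaves open:

- **Contact** means cell pressure strictly above a threshold (default
  0 kPa, configurable for noisy mats).
- **Band boundaries** for an axis of L rows sit at round(L/3) and
  round(2L/3) from the distal end; band lengths then differ by at most one
  cell for any L.
- **Areas are cell counts**, not pressure-weighted sums: the ratio is
  unit-invariant, and the pressure-weighted variant (the modified arch
  index) is deliberately out of scope.
- Footprints are oriented toes-up; `segment_thirds` accepts grids, float
  arrays or boolean masks.

Labeling: concave below the low cut-off, flat above the high one, the
boundaries themselves inclusive to normal.  Cohort fits use mean ± one
population standard deviation or Q1/Q3 (linear-interpolation percentiles);
both sets of statistics are stored on every fit for reporting.  A
degenerate constant cohort snaps σ to zero rather than keeping float-
rounding dust, so low = high exactly.

## Image preprocessing

1. **Detection.**  Pixels inside the foot color range are labeled into
   8-connected components; components under 50 px are discarded as speckle.
   Components are grouped by the image half holding their centroid — a
   coarse raster detaches toes from the sole, and the group is the foot.
   Each half must end up with exactly one foot object.
2. **Centering.**  Each foot's bounding-box center is translated (integer
   offsets, no resampling) to the center of its image half; the operation
   is idempotent.
3. **Rotation.**  The foot is split at its bbox row center; the medial-most
   pixel of each part (right edge for a left foot, left edge for a right
   foot; ties to the pixel nearest the part's row center) defines the
   medial line, and θ is its signed angle to the image vertical
   (+ counterclockwise).  When the mask has several components the largest
   (the sole) carries the line — detached toe blobs would otherwise swing
   the estimate by several degrees.  Correction rotates each half by −θ
   about the half center with bilinear interpolation and white fill.
   Because foot silhouettes are wider at the ball than the heel the medial
   line has a nonzero resting angle; recovery is therefore measured as the
   *change* of the estimate under a known rotation, and stays within about
   0.8° over ±15°.
4. **Toe removal.**  The high-pressure (red-range) region's centroid is the
   disk center; the radius R is the distance to the heel end (bottom-most
   foot pixel at the column nearest the centroid).  Everything outside the
   disk becomes background (logical AND with the disk mask); the disk is a
   full disk rather than a literal arc.  The grid-scale analogue
   `remove_toes_grid` takes cells at ≥ 2/3 of the frame maximum as the
   high-pressure region, matching where the red hue band begins in the
   colormap.  The disk test carries a 1e-6 slack so the heel anchor pixel
   itself is never cut by floating-point rounding.
5. **Contrast normalization.**  x' = (x − mean)/std with the population
   standard deviation; constant input returns zeros.  Per-image by default;
   the returned `Normalizer` re-applies training-set statistics to held-out
   data, which is how the feature pipeline normalizes (per feature, fit on
   the training split only).

## Features and selection

Fourteen per-foot scalars in three families: pressure statistics (sum,
mean, max, std over contact cells), contact areas (total plus the three
arch bands, identical to the segmentation), regional pressure ratios
(band pressure sums over total, summing to 1), and shape (axis length,
width, their ratio).  Selection correlates each feature with AI (Pearson)
and keeps |r| ≥ 0.2, inclusive, reported in descending |r|; zero-variance
features record r = 0 with a warning.  The model pipeline uses the top five
selected features per foot — on synthetic cohorts these are invariably the
midfoot/arch-driven ones.

## Pairing augmentation

n subjects give n left + n right records; mirroring each record onto the
other side doubles both lists (96 subjects → 192 per side), and the full
cross product forms 192 × 192 = 36,864 pairs labeled with the ordered
(left class, right class) subclass — nine subclasses when all three classes
occur on both sides.  Self-pairs are kept.  The faithful split mode
stratifies pairs by subclass only, which lets a physical subject contribute
pairs to both train and test; that leakage is logged, and a grouped mode
that assigns whole subjects to one side (dropping straddling pairs) is
provided for leakage-safe evaluation.

## Classifiers

- **k-NN**: Euclidean distance, default k = 7 (published search range
  [1, 1000]).  Distance ties at the k-th neighbor break by training index;
  vote ties break by the smaller mean neighbor distance, then class order.
- **CART**: Gini impurity G = 1 − Σp², split cost
  J = (m_l/m)G_l + (m_r/m)G_r minimized over all features and midpoint
  thresholds between consecutive distinct values; cost ties go to the
  smallest feature index then threshold; growth stops at max depth
  (default 9, range [0, 10]), purity, or when no split reduces impurity.
- **Image branch**: a classifier head (FC → dropout → softmax) on a
  configurable backbone.  The `tiny_test` backbone — one 3×3 convolution
  (8 filters), ReLU, 2×2 max-pool, a 64-node FC head — is implemented in
  the in-package numpy network engine (`plantar.nn`: im2col convolution,
  inverted dropout, RMSprop, seeded minibatching, early stopping) and
  trains on one CPU in seconds to minutes.  The `vgg16_style` preset
  (frozen through block 4, 1000 FC nodes, dropout 0.6, RMSprop 1e-5,
  224×224×3, nine classes) and `inception_style` (1024 nodes, dropout 0.6)
  carry the published fine-tuning hyperparameters but require a local
  pretrained checkpoint and raise a clear error otherwise — weights are
  never downloaded implicitly.  The quoted learning rate "10 × 10⁻⁵" is
  read as the conventional 1e-5 default; the literal 1e-4 reading is
  configurable.
- **Hyperparameter search** maximizes a caller-supplied objective over an
  integer range by grid or seeded random search; a Bayesian strategy
  delegates to scikit-optimize when installed and otherwise falls back to
  random search with a warning.  Ties resolve to the smallest candidate and
  the full trace is returned.

## Stacking and evaluation

Base models' class-probability vectors (not hard labels) form the metadata:
for each of 5 stratified folds, base models trained on the other folds
predict the held-out fold, so no metadata row comes from a model that saw
that sample.  The meta-network is one 1024-node hidden layer with dropout
0.3 and a softmax output, trained with RMSprop and early stopping on a 10%
validation slice.  Final base models trained on the whole training portion
produce test metadata.

Evaluation: stratified 80/20 outer split; stratified 5-fold on the 80%;
each fold-trained model scored on the common 20% test set; fold scores
summarized as mean/std/median/min/max.  The score is macro f1 — the
unweighted mean over classes of 2TP/(2TP+FP+FN) from one-vs-rest tallies —
chosen because the nine subclasses are imbalanced; an all-zero
denominator defines f1 = 0 with a warning.  Stratified folding delegates to
scikit-learn's StratifiedKFold (shuffled, seeded).

## Synthetic cohorts

A foot template is a sole silhouette (rounded forefoot block, midfoot
connecting band, rounded heel block) plus toe blobs separated by a gap of
empty rows.  The arch knob is `midfoot_band_fraction`: the middle third
keeps only that fraction of its width, anchored at the lateral edge so a
connected lateral column survives — the medial side is what narrows, as in
real concave footprints.  The analytic AI is an exact cell count on the
noiseless template with the same band rule as the scorer, making it a true
oracle; the fraction→AI map is a step function (integer cells), inverted by
bisection to hit target AI values to quantization.

High-pressure pads sit under the metatarsal heads and heel at 2.5× base
pressure (rendering in the red hue band; toes at 1.2× stay out of it).
The heel pad's extent is solved so the combined pad centroid lands midway
between "disk must cover the forefoot tip" and "disk must exclude the
toes", which makes toe removal correct by construction with ~2 cells of
margin under the default gap of 6 rows.

Perturbations: per-foot rotation (nearest-neighbor, halved with a warning
if the template would leave the half-grid), integer translation clamped to
bounds, and multiplicative lognormal noise with unit mean and the requested
coefficient of variation.  Left and right feet with the same seed are exact
mirrors; left/right frames occupy their own half of the 48-column grid.

Cohorts draw per-subject class targets from per-class AI bands
(concave 0.06–0.135, normal 0.205–0.245, flat 0.315–0.365).  The margins to
the fixed 0.17/0.28 cut-offs exceed both the template quantization and the
measured-AI error of the full chain (≤ 0.02), so classes are well separated:
no rasterization or noise event can flip a foot's label.  Both feet of a
subject share a class with a small within-subject target offset (SD 0.008);
per-subject foot length (28–34 cells) and widths vary so feature
distributions spread realistically.  Class counts follow the requested mix
by largest-remainder rounding.

What the generator does **not** emulate: biomechanically realistic pressure
distributions (real plantar pressure is not piecewise-constant), dynamic
gait, left/right asymmetries beyond the AI offset, sensor crosstalk, or
feet near the diagnostic cut-offs.  Passing tests therefore demonstrate the
pipeline's correctness and its behavior under the stated noise and pose
perturbations — not clinical performance on borderline human feet, which is
exactly where real cohorts are hard.

## Benchmark sizes and determinism

The standard benchmark generates 96 subjects at an equal class mix, builds
all 36,864 pairs, and materializes a subclass-stratified subsample of 720
pairs for model fitting; the image branch trains on 48×48 both-feet frames
for 20 epochs.  These sizes keep the full stacking evaluation (5 outer
folds × 5 metadata folds of image-branch training) to a few minutes on one
CPU while leaving every protocol element — stratified splits, out-of-fold
metadata, the common test set — intact.  All randomness flows from explicit
seeds: the generator, fold assignment, subsampling, network initialization
and minibatch order are reproducible run to run.

## Known limitations

- The device's native file format, exact colormap and interpolation are
  unspecified; the emulation is configurable rather than bit-faithful.
- The medial-line angle estimator uses discrete extreme pixels; on coarse
  rasters its absolute value carries a silhouette-dependent offset (its
  change under rotation is what is accurate).
- With full cross-pairing under the faithful split mode, high benchmark
  scores partly reflect subject overlap between train and test; the grouped
  mode quantifies the leakage-free setting.
- CART at the default depth can memorize small cohorts (zero test error on
  synthetic data); that is a property of the protocol, not a bug.
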