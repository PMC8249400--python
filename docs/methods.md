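# Methods

## The segmentation problem

The bony orbit (eye socket) appears in coronal CT and MRI slices as a closed
ring of bone around the orbital cavity.  Clinical questions — fracture
reconstruction planning, plate pre-bending, volumetric comparisons — need the
inner bony contour delineated on every slice of a volumetric scan, a task that
takes an expert minutes per slice by hand.  `orbitseg` implements a fully
automatic three-stage pipeline for this task, together with a synthetic
phantom generator that stands in for clinical data (which are private in this
setting), the evaluation metrics, and the cross-validation / ensemble
machinery needed to run a complete experiment.

## Pipeline

Per coronal slice:

1. **Global localization.**  The slice is intensity-normalized to [0, 1]
   (CT slices are first saturated at their 1st/99th intensity percentiles so
   sparse extreme-valued pixels cannot crush the usable contrast), cropped to
   the lateral half containing the studied orbit, and passed to a two-class
   U-Net trained to label the orbital region.  The probability map is
   thresholded at 0.5, holes are filled (8-connected foreground, 4-connected
   background), all but the largest connected component is discarded, and the
   component centroid becomes the proposed orbit center.  A fixed
   128 x 128 window around that center (clamped inside the slice) is the
   region of interest.  If no component survives, the nearest previously
   localized slice's center is reused; a volume with no localized slice at
   all is flagged and skipped.
2. **Boundary probability.**  A second U-Net, trained on ROIs with the
   rasterized orbit outline as target, predicts a per-pixel boundary
   probability map in which the orbit rim appears as a bright ring.
3. **Contour extraction.**  The ROI map is resampled onto polar axes about
   the proposed center (360 angle bins; radius bins of about one pixel up to
   the ROI half-diagonal), which unwraps the ring into a near-horizontal
   band.  Pixels are graph nodes; the edge between 4-connected neighbours
   `a, b` weighs `W_ab = 2 - (P_a + P_b)`, so high-probability ridges are
   cheap.  Two columns of near-probability-one padding are appended on each
   side, Dijkstra's algorithm finds the minimum-weight path between opposite
   corners of the padded image (diagonal moves are excluded — they make the
   radius drift), the padding is stripped, vertical excursions are collapsed
   to the radius at which the path exits each column rightward, and the
   per-angle radii are mapped back to a closed Cartesian contour, which is
   also rasterized to a filled region mask.

Per volume, each slice's mask is then averaged with its two neighbours
(pixel-wise 2-of-3 vote) to suppress isolated over- or under-segmentations;
the first and last slices, which lack a neighbour, are omitted from analysis.

Training uses subject-level k-fold cross-validation (every training subject
validates exactly once; the test subjects are fixed).  In ensemble mode the k
stage-2 maps are binarized at 0.5 and majority-voted (strict majority,
`ceil((k+1)/2)` votes) into a single map before contour extraction; stage-1
localization uses the first fold's model.  A fold whose probabilities never
reach 0.5 abstains from the binarized vote entirely, and with it a strict
majority can become unreachable; when the voted map comes out empty the
slice falls back to the ensemble-mean probability map (logged), so an
under-confident member degrades the ensemble gracefully instead of erasing
it.

## Networks and training

Both stages share one architecture: a U-Net with two 3x3
convolution + batch-norm + ReLU layers per block, 2x2 max pooling, a
dropout layer (rate 0.5) only at the bottleneck, nearest-neighbour
upsampling with skip concatenation in the decoder, and a 1x1 two-class head.
The network is fully convolutional and accepts any input whose spatial
dimensions are divisible by `2**depth`.  The reference configuration is
depth 4 with 64 base filters; the desk-scale profile uses depth 3 with 8
base filters.

The implementation is a compact channels-last numpy CNN framework written
for this package (conv / batch-norm / ReLU / max-pool / nearest-upsample /
dropout with explicit backward passes, Adam and SGD-momentum optimizers).
Convolutions are evaluated as nine shifted near-contiguous copies followed
by nine GEMMs, the formulation that makes BLAS-backed numpy fast enough to
train these networks on one CPU; backward passes are verified against finite
differences in the test suite.

Stage-specific recipes: stage 1 trains with Adam at learning rate 1e-3 for
100 epochs; stage 2 with SGD (momentum 0.9) at 1e-2 for 500 epochs; both use
per-pixel cross-entropy, mini-batch 128, re-shuffle every epoch, augment on
the fly (horizontal reflection with probability 0.5; rotation uniform in
±10°, bilinear for images, nearest-neighbour for masks, border filled with
the image minimum), and keep the parameters of the epoch with the best
validation accuracy (plain per-pixel accuracy over the validation subject).
Because boundary pixels are only ~2 % of a stage-2 ROI, the accuracy can sit
exactly at the all-background baseline for many epochs while the loss still
improves; checkpoint ties are therefore broken by the lowest validation
loss, which selects the most-converged epoch on such a plateau.
The desk profile shortens this to 30 / 60 epochs with batch 8, which one CPU
trains in about four minutes per fold.

Stage-2 ground truth is the orbit outline rasterized at 1-pixel thickness by
default; a config option dilates it to 3 pixels, which the desk profile uses
because an 8-filter network trained for 60 epochs on ~25 images learns the
wider target much more reliably.  Evaluation is always against the true
1-pixel contour and filled mask.

## Graph-search details

* Angle convention (single-sourced in `graphsearch`): θ = 0 along the +column
  axis, increasing counter-clockwise in (row, col) coordinates with row
  pointing down; a polar sample at (r, θ) reads the image at
  `(center_row − r·sinθ, center_col + r·cosθ)` by bilinear interpolation,
  with out-of-ROI samples reading 0.
* The radius axis covers (0, max_radius] with bin k at radius
  `(k+1)·max_radius/n_radii`; the angle ends are not wrapped — closure is
  imposed when the Cartesian contour is re-formed, mirroring the padding
  mechanism.
* Padding probability is `1 − 1e-5`: pad edges weigh `2e-5`, near-free but
  strictly positive so nonnegativity is trivially safe.
* Determinism: neighbours are expanded in the fixed order up, left, down,
  right from a stable heap, so equal-cost ties resolve identically across
  runs and platforms.
* The raw search quantizes radius to bins and, inside a saturated band of
  equal probabilities, may ride the band's edge (all paths tie).  Two
  defaults remove that bias: the probability map is pre-blurred with a
  1-pixel Gaussian, which peaks the ridge at the band center, and the found
  path is refined per column to the probability-weighted centroid of the
  radius bins within ±2 of the path (sub-bin resolution).  Both are
  configurable (`smooth_sigma_px`, `refine_subpixel`); with them the polar
  round trip on analytic circles of radius 10–60 px recovers the radius to
  better than 0.5 px mean error.
* A path whose mean on-path probability is below 0.2 (for example from an
  empty or flat map) is still returned but flagged low-confidence.

## Synthetic phantoms

The generator emulates exactly the properties the pipeline depends on, with
one orbit in the left half of each slice (matching the half-image crop) and
0.5 mm isotropic voxels recorded as metadata:

* **Geometry.**  Cross-section radius is maximal at the medial slice and
  decays geometrically by the `taper` factor per slice outward, so widths
  and heights are monotonically non-increasing away from the medial slice.
  The shape blends from a circle toward a rounded triangle with distance
  from the medial slice: `r(θ) = r·(1 + g·t·cos 3θ)/(1 + g·t)` with `t`
  rising linearly from 0 (medial) to 1 (end slices).  The default gain
  `g = 0.25` gives a 25 % radial modulation — a rounded triangle; larger
  values degenerate into 3-pointed stars that no longer resemble anatomy.
  Slice-to-slice center jitter (±2 px default) emulates anatomical drift.
  Masks are flood-filled after rasterization so every region obeys the
  8-connected-foreground / 4-connected-background pairing, the contour is
  extracted by Moore-neighbour boundary tracing (consecutive points are
  8-adjacent; rasterizing and flood-filling the contour reproduces the mask
  exactly), and ground truth is always noise-free.
* **CT style.**  Bright bone ring (0.95) on a uniform background (0.20),
  Gaussian noise (sd 0.02), and a 0.2 % scattering of extreme-valued pixels
  (dead at 0, hot at 8) that exercises the 1 %/99 % percentile saturation.
* **MRI style.**  Low-contrast ring (0.60 on 0.32 — Michelson ring/background
  contrast 0.30, less than half the CT's 0.65), a smooth ±25 % multiplicative
  bias-like field, Gaussian noise (sd 0.05), no extreme outliers, and a
  scatter of 20 smooth random blobs (amplitude ±0.2, σ 2–10 px) emulating
  the soft-tissue detail that clutters T1-weighted scans.  These choices make
  the MRI style measurably harder to segment than the CT style, reproducing
  the clinically observed ordering.
* **Cohorts.**  `generate_dataset` perturbs the template per subject (medial
  radius ±10 %, intensities ±5 %, triangularity ±20 %, fresh jitter stream)
  from a seeded sequence; everything is bit-reproducible for a fixed seed.

What the phantoms do *not* model: bilateral anatomy and skull context, the
open orbital entrance, fractures, partial-volume effects, scanner-specific
noise spectra.  Passing tests on phantoms therefore demonstrate that the
pipeline machinery (localization, boundary learning, polar graph search,
voting, metrics) works end to end on ring-like anatomy with realistic
contrast regimes — not clinical-grade performance on real scans.

## Evaluation metrics

Dice is computed per class — orbit and background — inside the 128 x 128
window around the orbit, both per slice (unweighted mean ± sd over evaluated
slices) and volumetrically, where the confusion counts are pooled over all
slices before the formula `2·TP/(2·TP + FP + FN)` is applied once (this is
not the mean of per-slice Dices, and the test suite pins a counting case
where the two differ).  Stage-1 quality is the Euclidean distance between
proposed and true centroid in pixels.  Boundary error is the mean over truth
contour points of the distance to the nearest predicted point (a symmetric
variant is available), reported in pixels and millimetres (× 0.5 mm at the
default spacing); the symmetric Hausdorff distance gives the worst-case
deviation.  Two empty masks count as Dice 1 (flagged); empty-versus-nonempty
as 0.  End slices removed by the volume post-processing are excluded
everywhere.

## Desk-scale experiment (tests and `scripts/acceptance.py`)

The package's own study conditions, chosen to fit a single CPU: per modality
style, 8 phantom subjects of 5 slices at 128 x 128 (6 training subjects in a
2-fold split, 2 fixed test subjects), depth-3 / 8-filter networks, stage 1
trained 30 epochs (Adam 1e-3), stage 2 60 epochs (SGD-momentum 1e-2), batch
8, ensemble by strict-majority vote over the 2 folds.  One fold trains in
about 4 minutes; the full two-modality experiment runs in roughly a quarter
of an hour.  The acceptance script reruns this experiment from scratch for a
given seed and writes the ensemble metrics (volumetric and per-slice Dice
for both classes, centroid error, boundary MAE, Hausdorff) as JSON.

## Known limitations

* The numpy networks are CPU-bound and desk-scale; the reference depth-4 /
  64-filter configuration is expressible but impractical to train here.
* Slice averaging by 2-of-3 vote necessarily clips the medial slice (a local
  area maximum) toward its neighbours' envelope; with the desk phantom's
  aggressive per-slice taper (0.92, five slices spanning the whole orbit)
  this costs a few percent of medial-slice Dice.  At clinically realistic
  per-slice taper (≈ 0.98 at 0.5 mm spacing) the effect is below 5 % of area,
  which the test suite pins.
* One orbit per scan; no DICOM input (TIFF slice series or multi-page TIFF
  only); no 3-D surface reconstruction.
* The polar search assumes the proposed center lies inside the true contour;
  grossly failed localization degrades stage 3 (the low-confidence flag
  marks, but does not repair, such slices).
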