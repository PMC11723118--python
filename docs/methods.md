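# Methods

## Problem

Morphometric phenotyping of zebrafish larvae (~120 h post-fertilization,
bright-field microscopy, one laterally oriented larva per image) is cast as
single-animal keypoint detection: 26 named landmarks on organ boundaries and
body extremities (muzzle tip, caudal-fin apices, eye / ear / swim-bladder
extrema, yolk-sac and pericardium junctions).  Unlike human-pose joints,
these landmarks sit on *contours*, so the package implements target
encodings and a feature extractor designed for thin, elongated, strip-like
structure.

## Pose normalization

Raw images show the larva at arbitrary rotation, position, scale and
dorsoventral side.  A similarity transform (flip -> rotate -> scale ->
translate, serialized as a 3x3 homogeneous matrix) is fitted from three
anchors: points 1 (muzzle) and 4 (first caudal-fin vertex) define the body
axis, point 5 (second caudal-fin apex) the flip.  The canonical constraints
are: points 1 and 4 on the horizontal centre line, midpoint at the canvas
centre, distance equal to `target_length_fraction * width`, and point 5
below the axis (back up, belly down).  Defaults: canvas 384x288,
`target_length_fraction = 0.7` (the equal-length constraint fixes only that
all images share one length; 0.7 leaves margin for fins).  Raster
resampling is bilinear; canvas exposed beyond the source image is filled
with the median border intensity.  Fitting is exact (closed form), so
normalization is idempotent and recovers a synthetically posed larva's
canonical layout to well below 0.5 px.

Anchors on unannotated images come from the same network configured with 3
output channels and trained on the 3-point task.

## Target encodings

With output stride 4 (targets at w/4 x h/4, matching the highest-resolution
branch of the backbone):

* **Isotropic heatmap** — `h = exp(-(dx^2 + dy^2) / (2 sigma^2))`,
  truncated to zero outside the 3-sigma box, centre quantized to the
  nearest heatmap pixel so the peak value is exactly 1.
* **Anisotropic heatmap** — separate per-axis sigmas,
  `h = exp(-(dx^2 / (2 sx^2) + dy^2 / (2 sy^2)))`, per-axis 3-sigma
  truncation.  The default rule sets the long-side sigma exactly one higher
  than the short side, long axis along x: after pose normalization most
  organ contours run near-horizontally, and the encoding tolerates error
  parallel to the contour more than perpendicular to it.
* **Cross-shaped heat tensor (CSHT)** — per keypoint one width vector and
  one height vector, each a 1-D Gaussian (default sigma 1) peaked at the
  keypoint's axis coordinate; the 2-D map is recovered as the outer
  product.  Pooling a 2-D map to its axis marginals (column/row means,
  renormalized to peak 1) and the outer-product reconstruction are exact
  inverses on rank-1 peak-1 maps.

Decoding is per-axis argmax (ties toward the lowest index) with optional
parabolic sub-pixel refinement from the peak's two neighbours (offset
clamped to half a bin).  For 2-D heatmaps, whose predicted blobs are broad,
refinement is applied along the argmax row and column.  The vector lengths
default to w/4 and h/4 (the head's feature resolution); this is exposed as
configuration because the alternative vector resolution w/2 + h/2 is not
derivable from the layer table the architecture follows.

## Network

A bottleneck-style stem (two 3x3 stride-2 conv-BN-ReLU units, reaching
w/4 x h/4) feeds four **combinatorial convolution blocks**: bottleneck
blocks whose middle 3x3 stage is augmented by chained pairs of 1xN / Nx1
strip convolutions (N = 5, 7, 9).  Each vertical strip convolution
receives, besides its horizontal partner's output, the outputs of all
smaller-scale branches (inner shortcuts), so the receptive field grows into
tall/wide rectangles suited to the larva's elongated body; with all strip
branches zeroed the block reduces *exactly* to a plain bottleneck.  The
reduction `x` is a 1x1 channel reduction to a quarter of the input
channels (the bottleneck reading; a spatial crop would not be summable).

Then follow four multi-resolution integration/transition stages in the
high-resolution-network style: stride-2 3x3 transitions open new branches
(up to four, at strides 4/8/16/32), each branch runs a basic residual
block, and all-to-all fusion sums stride-2 conv chains (downward) and
1x1-conv + nearest-upsampling paths (upward).  Branch widths follow the
published W32 recipe for variant **B** (32/64/128/256) and W48 for variant
**L** (48/96/192/384).  A final 1x1 convolution maps the highest-resolution
branch to 26 channels.

The **CSHT head** average-pools each channel to its width and height
vectors, lays the two side by side into one length-(W+H) vector per
channel, mixes across the 26 channels with a 1x1 convolution, applies a
short per-axis 1-D filter (kernel 3, zero-initialized bias), and splits the
vectors back.  Mixer and filter initialize to identity/delta, so an
untrained head is exactly the pooling operator; the under-specified
post-split "filter" is deliberately the smallest learnable choice and is
exposed as configuration.  In heatmap mode the 26 channels are the output.

The network, batch-norm, and Adam are implemented on a small numpy
reverse-mode autodiff engine inside the package (`larvapose.nn`);
convolution is evaluated as a sum of shifted tensordot contractions, which
is exact and memory-flat for the small rectangular kernels used here.
Weight initialization is He-normal for convolutions, unit/zero for norms;
batch-norm uses eps 1e-5, momentum 0.1.

## Training

MSE objective: sum of squared differences over all keypoints divided by
(M * w * h); in CSHT mode the same formula per axis, combined with equal
weights by default.  Reference schedule: Adam, batch size 24, 120 epochs,
learning rate 0.001 dropped to 0.0001 at epoch 40 and 0.00001 at epoch 80
(1-based).  No augmentation by default.  Model selection uses mean
validation OKS (best and last checkpoints are both kept).  Training aborts
on a non-finite loss.  Fixed seed + single-threaded execution reproduce the
loss trajectory bitwise.

## Evaluation

OKS per larva is the visibility-weighted mean of
`exp(-d_i^2 / (8 s^2 sigma^2))` with `s^2` the ground-truth bounding-box
area (floored at 1) and sigma = 0.0125 by default; sigma is configuration
because the reference-scale constants behind it are not reconstructible.
`sigma_from_threshold(d, s, t) = d / (2 s sqrt(-2 ln t))` is the exact
single-keypoint inversion.  With one instance per image, precision- and
recall-type counts coincide whenever every image yields a prediction, so
the two reported summaries use deliberately distinct conventions, both
labelled in reports: AP_t is the fraction of images with OKS >= t, AR_t
the fraction of individual keypoints whose own exp term is >= t; mAP / AR
average over thresholds 0.50:0.05:0.95.  Note that the bounding-box scale
is axis-aligned, so OKS is invariant under joint scaling/translation/flip
but not under joint rotation.

## Synthetic data

The generator renders a spindle-shaped body along a (optionally bowed)
horizontal midline with ellipse organs and a small caudal fin, plus
background gradient, mild vignetting and additive Gaussian noise —
grayscale replicated to RGB, emulating the bright-field appearance class
without photorealism.  All 26 keypoints are derived in closed form from the
shape model (organ extrema exactly on their ellipse axis endpoints), and the
identity-pose layout coincides with the pose-normalization target frame, so
generation -> random pose -> normalization is an exact round trip.  Poses
sample rotation, scale, translation and vertical flip; "easy mode"
(high contrast, rotation within ±0.12 rad, scale 0.92–1.05, no flips) exists
for fast CPU training runs.  What passing tests on this generator do *not*
show: robustness to real-microscope artefacts (debris, defocus, uneven
illumination beyond a linear gradient, touching or deformed larvae) or to
annotation noise.

## Desk-scale study sizes

CPU-scale experiments (tests and the acceptance script) use 96x72 images,
about 200 easy-mode training larvae, and the "tiny" network configuration
(stem 16 channels, one strip-conv block, two branches 16/32).  The CSHT
head reaches ~1.3 px mean decoded error after 60 epochs; the heatmap head
converges more slowly on this tiny configuration and uses a longer
schedule.  Full-scale B/L variants are constructed and verified for shape
and ordering contracts but not trained here.

## Known limitations

* Single larva per image by design; no multi-instance matching.
* Printed parameter counts of the reference architecture family are
  internally inconsistent across published tables, so parameter counts are
  validated by ordering (B < L) and hand-enumerated toy cases only.
* The numpy engine is single-device and eager; it is sized for desk-scale
  experiments, not for full 4k-image training runs.
* OKS scale uses the axis-aligned bounding box (see above).
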