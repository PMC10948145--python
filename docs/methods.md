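# Methods

## Overview

`apodetect` detects apoptotic cell-death events in single-channel
timelapse microscopy.  Detection is framed as activity recognition in
space and time: a candidate-region proposer nominates boxes per frame, a
sequence classifier decides whether the short clip around each box shows
the apoptotic morphological program, surviving boxes are thresholded and
de-duplicated by non-maximum suppression, and a centroid tracker links
per-frame detections into one track per death event.  The package also
contains the training machinery (crop extraction, fixed-length sampling,
2D and volumetric augmentation, hard-negative mining), the scoring tools
(TPR/FPR against point annotations, nearest-neighbor analysis, cumulative
curves, a graph-edit tracking score, a movie quality score) and a 4PL
dose–response fitter for toxicity assays built on the detector's counts.

## The sequence classifier

The classifier consumes K = 5 grayscale 59 × 59 crops of the same
location at increasing frames and outputs a two-way softmax.  The
architecture is a time-distributed convolutional front end — three
blocks of 3 × 3 same-padding convolution → ReLU → batch norm → dropout
0.3 → 2 × 2 max pooling, applied with shared weights to each frame —
whose per-frame features are flattened, linearly projected to tokens,
summed with learned positional embeddings, and passed through a stack of
pre-norm self-attention blocks (multi-head attention + feed-forward,
residual connections).  The token sequence is then pooled and classified
by a ReLU/dropout MLP ending in the softmax.

Full-scale defaults: conv widths 64/128/256, 4 attention blocks, 6
heads, MLP 1024/512/128/64, two-class cross-entropy, Adam at learning
rate 1e-4, batch 32, checkpoint on best validation accuracy, early
stopping with patience 15, learning-rate halving on a validation-loss
plateau.  Unstated details resolved here: token width 240 (the nearest
multiple of six heads to a 256-wide projection), feed-forward width
2 × token, pre-norm residual blocks, inputs scaled to [0, 1] by
division by 255, plateau reduction factor 0.5 with patience 5 epochs.

**Sequence pooling.** The pooled representation fed to the MLP is the
*concatenation* of the K tokens (config `pool="concat"`; `"mean"` is
also available).  Concatenation is order-preserving: with mean pooling
the network can only recover frame order through the positional
embeddings inside attention, and in practice it then tends to classify
by content alone.  Because apoptosis is a *directed* process — a
reversed clip is not an event — the order-preserving head is the
appropriate default, and the temporal-sensitivity check below verifies
the behavior.

**Implementation.** The network, backpropagation and the Adam optimizer
are implemented directly in NumPy (im2col convolutions in channels-last
layout, manual gradients for every layer, global-norm gradient clipping
at 5, linear learning-rate warmup over the first epoch).  Gradients are
verified against finite differences in the test suite.  Training is
fully deterministic under a seed.

Three training-procedure details matter at small data sizes.  (1) The
best-validation-accuracy checkpoint keeps the *latest* epoch tying the
maximum: among equally accurate checkpoints the longer-trained one has
more confident, better-separated probabilities, which the stringent
0.995 deployment threshold requires.  (2) Each training clip is, with
probability 0.5, given one random shift/zoom/rotation/flip draw per
epoch (the same transform on all K frames), mirroring the loader-level
augmentation; this removes the border-location failure mode of
unaugmented runs.  (3) `TrainConfig.n_restarts` optionally runs seeded
restarts and keeps the best-validating one, because few-hundred-step
runs are sensitive to the initialization basin.

**Desk scale.** The experiments that the tests and the acceptance
script run use a reduced preset (`ModelConfig.small()`: conv widths
6/12/24, token width 48, 2 attention blocks × 4 heads, MLP 128/64,
~0.5 M parameters) and a learning rate of 1e-3.  These runs see a few
hundred optimizer steps rather than the tens of thousands of a
full-scale training, so the model and step size are scaled together;
the topology (time-distributed convs → attention → MLP) is unchanged.

## Synthetic movies

The generator renders ground-truthed movies in two regimes.

*In vitro* — a near-confluent monolayer of nuclei on a jittered grid,
each an anisotropic 2D Gaussian (radius 6 ± 1 px, peak ≈ 150 on the
8-bit scale, per-frame intensity jitter 3%).  An apoptotic nucleus
shrinks linearly to 0.42 × its radius over 8 frames (the default event
duration, matching the median duration of the morphological changes in
this kind of data) while its peak brightness rises as 1/scale² —
integrated fluorescence is conserved under chromatin condensation, with
clipping at 255 playing the role of detector saturation.  So the two
annotated hallmarks hold by construction: nuclear area falls while
pixel-intensity SD rises.  The nucleus then fragments into 2–4 small
bodies that fade to faint persistent debris.  Mitotic confounders are
rendered with condensation followed by two daughters that start small,
bright and condensed and then grow and dim — the temporal mirror of
apoptotic condensation, as in real dividing cells.

*In vivo* — sparse motile cells placed by rejection sampling, Brownian
motion (configurable step), arrest at event onset, transient peripheral
blebs during the event, then fragmentation.  Noise can be specified
directly (additive Gaussian, default SD 4) or via a target SNR: the
generator calibrates the noise against the package's own SNR estimator
by fixed-point iteration, which the loop-back test verifies to within
20% at the reference value 8.9.

Ground truth records each event's centroid and start frame (beginning
of shrinkage/blebbing) plus every cell's trajectory.  All randomness
flows from one seeded generator; equal seeds give bit-identical movies.

**Clip library.** Positives are 59 × 59 clips centered mid-event.
Negatives mix healthy cells (~30%), background locations at least 40 px
from any event (15%), mitotic confounders (20%), residual debris from
earlier events (20%), and time-reversed event clips (15%).  The last
three matter: with only location-based negatives the synthetic task is
spatially separable and a trained network ignores frame order entirely.
Debris teaches "fragments present ≠ event happening", mitosis teaches
"condensation direction matters", and reversed clips state outright
that the mirror-image process is not apoptosis.  These are properties
of real negative data (debris and dividing cells populate real class-0
sets); the reversed clips are a standard temporal-order negative from
action recognition, exposed as `include_temporal_negatives`.

**What the generator does not emulate** — real chromatin texture,
imaging artifacts (drift, focus loss, uneven illumination),
autofluorescent structures, cell crowding with physical contact, and
the full morphological heterogeneity of real nuclear fragmentation.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that the classifier can learn a directed spatiotemporal
signature at realistic SNR and density; they do not certify accuracy on
real microscopy, which requires training on annotated real data.

## Region proposal

Two proposers share the same downstream filters (both box edges within
[20, 40] px inclusive; mean 8-bit intensity ≥ 40):

* *selective-search style*: Felzenszwalb over-segmentation followed by
  greedy merging of adjacent regions by intensity and size similarity
  (grayscale movies have no color channels), emitting a box per region
  at every merge level.
* *blob* (default): Otsu threshold → connected components, with one box
  per local intensity maximum rather than per component — confluent
  nuclei merge into single components whose bounding box drifts off
  every cell, while intensity peaks stay put.  Box edges derive from
  the component's area share per peak, clamped to [20, 40].

The brightness cutoff of 40 interacts with the physics above: a
condensed nucleus passes it only because condensation concentrates its
signal; without brightness conservation late-event proposals die at
this filter.

## Deployment

For frame t, each accepted box yields a clip cut from the nine-frame
window centered on t (the expected event duration), clamped at the
movie edges by replication and uniformly subsampled to K = 5 (first and
last window frames always included; ties in the index rounding go up).
Boxes with P(apoptotic) ≥ 0.995 (the stringent monolayer default; 0.95
for intravital data) enter per-frame greedy NMS: IoU strictly above 0.1
suppresses, ties in probability break by input order.  Detections link
into tracks by greedy nearest-neighbor assignment in increasing
distance (threshold 10 px, ties by lower track id), a track closes
after more than 3 missed frames (the gap parameter), and tracks shorter
than 2 detections are discarded.  A track's event time is its first
frame; its location is the median of its centroids.

## Evaluation

Event matching is one-to-one greedy in the combined normalized distance
(spatial/20 px + temporal/5 frames), accepting pairs within both radii;
the radii are config-exposed since annotation tolerances vary.  TPR is
matched truth / all truth; FPR is unmatched predictions / all
predictions (undefined TPR on empty truth is reported as missing).  The
nearest-neighbor analysis reports each prediction's distance to the
closest truth event against a uniform-random baseline of equal count.
TRA follows the Cell Tracking Challenge AOGM construction: per-frame
minimum-cost one-to-one correspondence within 10 px, then
TRA = max(0, 1 − AOGM/AOGM₀) with weights FN = 10, FP = 1, EA = 1.5,
ED = 1 (NS and EC are exposed but inert without divisions), AOGM₀ being
the cost of building the truth graph from nothing.

The movie quality score averages five unit-scaled components — cell
count, SNR, temporal fluctuation of the frame mean, mean shortest
inter-cell distance, saturated-pixel fraction — each oriented so higher
is better over reference ranges taken from the spread of intravital
movies (cell count 87 ± 76, SNR 8.9 ± 3.6, shortest distance
21.2 ± 15.4 µm).  The composition is a documented surrogate: the exact
weighting behind the original score is not published.  SNR is the Otsu
foreground mean over a MAD-robust background SD (robust because dim
cell fringes leak into the background class), capped at 100 for
effectively noise-free backgrounds.

## Volumetric augmentation

Scarce volumetric event sequences expand by random 3D rotation: a
uniform unit axis and a uniform angle in [0°, 45°] per draw, the same
rotation applied to every frame of a sequence, trilinear interpolation
on an isotropic grid, out-of-volume samples filled with the volume's
median background, maximum projection along z, symmetric padding to the
pre-rotation footprint, and center-crop/pad to 59 × 59.  A 0° draw
reproduces the plain projection to within interpolation rounding
(≤ 2 gray levels), and 100 draws per input give the hundredfold
expansion used for scarce intravital annotations.

## Dose–response

Counts per condition and timepoint feed a four-parameter log-logistic
fit, y = bottom + (top − bottom)/(1 + (EC50/x)^hill), with dose 0
anchoring the bottom asymptote (optionally fixed to the vehicle
response).  Fitting is trust-region least squares multi-started over
log-spaced EC50 initials and two Hill starts; negative slopes are
allowed only when requested.  Exact recovery on noise-free
self-generated data and a 200-replicate Poisson simulation study
(8 doses × 3 replicates, top ≈ 300 counts, median relative EC50 error
below 10%) bound the estimator's behavior at realistic counting noise.

## Problem sizes used by the tests and the acceptance script

Classifier runs train on 500 clips per class for 20 epochs at batch 32
with a 0.12 validation split, and report accuracy on a 20% held-out
split (n = 200).  The detection benchmark is one 256 × 256 × 100 movie
with ~100 nuclei and 30 planted events, processed with all deployment
defaults (window 9, threshold 0.995, NMS 0.1, gap 3, distance 10).  The
end-to-end determinism check runs a reduced chain (200 clips/class,
12 epochs, a 160 × 160 × 48 movie) twice and compares the complete
summary JSON.  These sizes are the package's chosen experiment scale;
all of them are plain function arguments and can be raised freely.

## Known limitations

* Synthetic-data results bound correctness of the machinery, not
  real-data accuracy (see the generator's non-goals above).
* The NumPy network trains small models efficiently but is not suited
  to the full 64/128/256 architecture at realistic dataset sizes; that
  regime expects a GPU framework, and the checkpoint format would carry
  over.
* The tracker is nearest-neighbor with gap closing; it does not model
  motion (no Kalman prediction) and cannot resolve crossing events
  closer than the distance threshold.
* Per-frame NMS does not merge detections across frames; the tracker is
  the only cross-frame association step.
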