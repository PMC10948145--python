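# apodetect

Spatiotemporal detection of apoptotic cell death in live-cell imaging.

Apoptosis has a stereotyped morphological program — nuclear shrinkage
and chromatin condensation, membrane blebbing, fragmentation into
apoptotic bodies — that unfolds over minutes in timelapse microscopy.
Classical readouts (fixed-sample staining, flow cytometry, fluorescent
reporters) either destroy the temporal dimension or require a dedicated
channel.  `apodetect` instead treats death detection as activity
recognition on the image sequence itself: it reports *where* and *when*
each cell died in a single-channel movie, with no extra probe.  It is
aimed at quantitative cell biologists running monolayer (epithelial
nuclei) or intravital (leukocyte) timelapses, and at methodologists who
need a fully synthetic, ground-truthed sandbox for detection pipelines.

## The method

For every frame, candidate regions of interest are proposed
(selective-search-style region merging, or a peak-splitting blob
detector), filtered to boxes with edges in [20, 40] px and mean 8-bit
intensity ≥ 40.  For each accepted box at frame *t*, a clip of K = 5
crops (59 × 59 px) is cut from the nine-frame window centered on *t*
and classified by a **Conv-Transformer**: time-distributed convolutions
(3 × 3 kernels, widths 64/128/256, ReLU + batch norm + dropout 0.3 +
2 × 2 max pooling per block) extract per-frame features, which become
tokens with learned positional embeddings, pass through multi-head
self-attention blocks (6 heads), and feed an MLP (1024/512/128/64) with
a 2-way softmax:

    P(apoptotic | clip) = softmax(MLP(Attn(Conv(frame_1..K))))

Boxes with P ≥ 0.995 survive greedy non-maximum suppression (IoU > 0.1
suppresses) and are linked into tracks by nearest-neighbor centroid
matching (distance ≤ 10 px, gap ≤ 3 frames, tracks of < 2 detections
dropped) — one track per death event.  Downstream tools score
predictions against (x, y, t) point annotations (TPR/FPR,
nearest-neighbor distances, temporal offsets, cumulative-curve Pearson
r, an AOGM-based tracking accuracy TRA), summarize movie quality, and
fit four-parameter log-logistic dose–response curves
`y = bottom + (top − bottom)/(1 + (EC50/x)^hill)` to apoptotic counts
for toxicity assays.

The network, backpropagation and Adam live in pure NumPy — gradients
are verified against finite differences in the test suite — and every
stage is deterministic under a seed.  A synthetic-movie generator
renders ground-truthed monolayer and intravital phenomenology
(shrinkage with conserved integrated fluorescence, fragmentation into
fading debris, mitotic confounders, Brownian motility) so the entire
pipeline trains and evaluates without any data download.  See
`docs/methods.md` for the model details and design rationale.

## Worked example

Generate a movie, train on a synthetic clip library, detect, track and
score — all in one command:

```sh
apodetect end2end --seed 5 --out-dir runs/demo
```

which trains a desk-scale classifier (200 clips/class, 12 epochs) and
prints the evaluation summary of the detector on an unseen synthetic
movie (192 × 192 px, 60 frames, 55 cells, 12 planted deaths):

```json
{
  "fpr": 0.0,
  "mean_abs_temporal_offset_frames": 3.6666666666666665,
  "mean_nn_distance_px": 0.8288557290689607,
  "mean_spatial_error_px": 0.8288557290689607,
  "mean_temporal_offset_frames": 3.6666666666666665,
  "n_detections": 18,
  "n_matches": 6,
  "n_pred": 6,
  "n_tracks": 6,
  "n_truth": 12,
  "n_truth_events": 12,
  "pearson_r": 0.9666504649378468,
  "seed": 5,
  "sequence_accuracy": 0.9625,
  "tpr": 0.5,
  "tra": 0.13693098384728342
}
```

Reading it: the classifier separates apoptotic from nonapoptotic clips
with 96% held-out accuracy; every emitted track matches a planted death
(zero false positives, FPR 0) with sub-pixel spatial error and a
+3.7-frame offset (detections fire at nuclear disruption, annotations
mark shrinkage onset); the quick 12-epoch model is deliberately small,
so only half the events clear the stringent 0.995 probability
threshold — the full-length training used by the test suite and
`scripts/acceptance.py` (500 clips/class, 20 epochs) clears an
event-level TPR of 0.8 at the same defaults on a denser movie.  The individual
stages are also available as `synth`, `build-dataset`, `augment3d`,
`train`, `detect`, `track`, `evaluate` and `dose-response` subcommands
composing through TIFF/HDF5/CSV/JSON artifacts, or as the library API
(`apodetect.generate`, `ConvTransformerClassifier`, `detect`, `track`,
`match_events`, `fit_4pl`, ...).

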