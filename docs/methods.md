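# Methods

This note records the scientific and numerical choices behind `fees-xai`:
what is modeled, which parameters matter, what the synthetic scenes do and
do not emulate, and where the design was genuinely open.

## Problem and model

The task is frame-wise multi-structure segmentation of endoscopic
swallowing videos with three overlapping classes — glottis region of
interest (ROI), vocal cords, and aspirated bolus — followed by frame-level
aspiration detection and a timeline that surfaces consecutive-frame
detections for human verification. Segmenting the anatomy alongside the
bolus serves two purposes: the glottis and cords are much easier to learn
and anchor the harder bolus class spatially (a real aspiration always lies
inside the ROI), and the segmentations themselves are the explanation a
clinician verifies.

The segmentation model is a 2D U-Net: an encoder of `depth` levels whose
channel count doubles from `base_filters` per level (two 3×3 zero-padded
convolutions, each followed by batch normalization and PReLU, with 2×2 max
pooling between levels), and a mirror decoder using ×2 nearest-neighbor
upsampling, a 3×3 convolution, concatenation with the encoder skip, and a
convolution block with channel-wise dropout. A final 1×1 convolution with
per-channel sigmoid yields three probability maps at input resolution.
Because the classes overlap, the heads are independent (multi-label); a
softmax would force mutual exclusivity and could not represent a bolus
pixel that is also ROI.

The network, loss, and Adam optimizer are implemented directly on NumPy
(channels-last tensors; convolutions as nine shifted GEMMs with explicit
backward passes, verified against finite differences in the test suite).
This keeps the package dependency-light and CPU-friendly at the scales it
targets; it is not intended for large-scale GPU training.

## Training procedure

* **Loss.** Soft Dice, `1 − mean_c (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1.0
  in the loss. Evaluation metrics use the exact set formulas with no
  smoothing (both-empty masks score 1.0 by convention; frame-level
  emptiness is judged by the detection metrics instead).
* **Sampling.** Patches are drawn stratified: P(ROI patch) = 0.8,
  P(aspiration | ROI) = 0.25, remainder from frames labeled as not showing
  the glottis. ROI patches are centered on a uniformly drawn ROI pixel and
  clamped to bounds, which guarantees the stratum contract; negative
  patches are positioned uniformly and carry all-zero targets.
* **Augmentation** is applied online per draw (rotation, zoom, mirror,
  contrast, brightness), with one shared geometric transform for image and
  masks (bilinear vs. nearest interpolation). Brightness shifts are bounded
  by ±25% of the patch mean; zoom is in-only up to ×1.5. Rotation range
  ±30° and contrast range [0.75, 1.25] are package defaults, exposed in
  the configuration. If a warp pushes a small glottis target out of the
  patch, the sample is demoted to the negative stratum rather than
  violating the stratum invariant.
* **Early stopping.** Every `val_interval` iterations the per-class
  Jaccard against all validation frames is computed (per frame, skipping
  frames where both reference and prediction are empty for that class,
  then averaged per class and across classes). Improvement means a strict
  increase of the mean Jaccard with no minimum delta; after `patience`
  validations without improvement, training stops and the best recorded
  state (weights plus batch-norm statistics) is restored.

Reference-scale defaults are `base_filters=32, depth=4`, patch 352×288
(the ×2-downscaled resolution of 704×576 interlaced recordings), batch 16,
learning rate 1e-4, `val_interval=500`, `patience=15`.

## Desk-scale study conditions

All self-contained experiments (test suite, acceptance script) run a
reduced configuration chosen once: scenes of 192×192 px and 200 frames
(two training videos, one validation video subsampled to every 5th frame,
one held-out video), network `base_filters=8, depth=3`, patch 96×96
(the full downscaled frame), batch 8, learning rate 1e-3, validation every
50 iterations, patience 15, at most 2000 iterations. The larger learning
rate and denser validation schedule are the standard rescaling for a net
two orders of magnitude smaller than the reference configuration; 2000
iterations suffices for all three classes to converge on these scenes.
On one CPU a full round takes roughly 15 minutes. The learning dynamics
reproduce the qualitative signature of the clinical task: anatomy classes
rise within a few hundred iterations, the aspiration class only after
~850, because positive bolus pixels are rare and variable.

## Synthetic scenes: what they emulate, and what not

Each generated video renders, over a textured vignetted tissue background:

* a dark elliptical glottis whose minor axis oscillates with
  `open_close_period` (open/closed states are labeled), absent per frame
  with probability `1 − visibility_schedule`, and occasionally shifted to
  the image edge (`partial_visibility_rate`) so that it is clipped — a
  known failure mode of ROI segmentation near borders;
* two brighter vocal-cord bands flanking the glottis;
* bolus events placed by a seeded uniform schedule (`bolus_event_rate`
  events per 100 frames, durations 3–10 frames, overlapping intervals
  merged), rendered as blob clusters inside the ROI whose area follows a
  grow–shrink envelope within `bolus_size_range`. Three appearance types
  mirror the clinical bolus consistencies: slurry (textured
  mid-intensity), saliva (small, bright), liquid (translucent,
  low-contrast);
* acquisition noise: brightness jitter, Gaussian blur, and saturated
  specular reflections (a classic source of false bolus detections).

Masks are rasterized from the same geometry as the image, so annotations
are exact, and the event log is reproducible independently of rendering
(event placement, visibility, geometry and pixel noise consume separate
seeded RNG streams). Structural invariants hold by construction: the
aspiration mask is a subset of the ROI mask, and the frame-level
"glottis visible" label is true exactly when the ROI mask is nonempty.

The generator reproduces the *structure* of the data, not its appearance
statistics: no pharyngeal anatomy beyond the three classes, no interlacing
(the ×2 downscale is still applied for pipeline fidelity), no photometric
realism. Passing end-to-end tests therefore demonstrates that the
pipeline's machinery — sampling, optimization, post-processing, metrics,
timeline — recovers known ground truth under controlled difficulty; it
does not certify clinical performance, which the private corpus showed to
be substantially harder for the bolus class.

## Numerical and convention choices

* Coordinates are row-major, 0-based; pixel (i, j) = (row, column).
* Binarization threshold 0.5 with `≥` on the boundary; configurable.
* Connected components use 8-connectivity by default (robust to
  single-pixel diagonal gaps in thresholded sigmoid output; 4-connectivity
  available). Ties between equal-size components are broken
  deterministically toward the component containing the first foreground
  pixel in scan order.
* ROI restriction uses the glottis mask *after* largest-component
  selection.
* Detection outcome of a frame with a nonempty prediction, a nonempty
  reference, and zero overlap: counted as one false positive *and* one
  false negative (the detector both missed the true bolus and raised a
  spurious one). These frames are tallied separately (`mismatches`) so the
  convention is auditable; the true-positive rule itself (any positive
  Dice overlap) only defines the TP side.
* The false-positive frame criterion on glottis-free frames is ≥1 pixel
  after post-processing — the strictest reading — with a configurable
  pixel threshold.
* `detect_event_runs` defaults: `min_consecutive=3`, `min_pixels=1`
  ("several consecutive frames" made concrete); `peak_frame` is the
  earliest argmax within a run.
* Dataset splitting is per video (frames of one video are correlated);
  validation/test counts are `round(fraction·n)` with the remainder to
  training. The 92-video corpus at fractions (0.772, 0.065, 0.163) yields
  71/6/15.
* Dice smoothing ε = 1.0 in the loss only; 0 in evaluation.
* Videos are stored as lossless multipage TIFF stacks or PNG frame
  directories; masks as one PNG per class (0/255); labels and indices as
  JSON/JSONL. Classes are stored as separate masks because they overlap.

## Known limitations

* The corpus summary table records 1029 + 103 + 199 = 1331 segmented
  frames while the prose total elsewhere is 1330; the table values are
  used as-is.
* No temporal modeling: each frame is segmented independently; temporal
  smoothing or recurrent extensions are out of scope.
* No morphological cleanup (hole filling, minimum blob size) beyond the
  largest-component/ROI restriction.
* The NumPy network is single-threaded BLAS-bound; reference-scale
  training (32 base filters, 352×288 patches) is possible but slow on CPU.
* Synthetic event recall is measured against the generator's own event
  log; at clinical scale the analogous quantity depends on annotation
  protocols not modeled here.
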