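# fees-xai

Explainable, frame-by-frame aspiration detection for endoscopic swallowing
videos (FEES — Flexible Endoscopic Evaluation of Swallowing).

Aspiration — swallowed material passing the vocal cords into the airway —
is the key finding a FEES examiner looks for, and it is easy to miss during
a long examination. This package implements a segmentation-based detection
pipeline whose every decision a clinician can verify: instead of a
per-video black-box label, it segments the relevant anatomy (the glottis
as region of interest, the vocal cords) and suspected boluses in every
frame, and surfaces *meaningful frames* — stretches of consecutive frames
with detected aspiration — on a pixel-count timeline for human review.

The clinical corpus behind this design is private, so the package ships a
synthetic scene generator that reproduces the structure of the data
(oscillating, intermittently absent glottis; flanking vocal-cord bands;
bolus blobs of three appearance types; reflections and brightness/sharpness
variability) with exact ground truth, making the whole pipeline testable
end to end.

## Pipeline

1. **Preprocessing** — frames are downscaled ×2 (2×2 block averaging) to
   remove comb artifacts of interlaced recording; masks follow by 2×2
   max-pooling.
2. **Segmentation** — a 2D U-Net (zero-padded convolutions, 32 base
   filters doubling per level, batch normalization, PReLU, dropout) with
   three independent sigmoid output channels: glottis ROI, vocal cords,
   aspiration. Classes overlap (a bolus lies inside the ROI), so the heads
   are multi-label rather than softmax. The network is implemented directly
   on NumPy with explicit backprop and runs on CPU.
3. **Training** — Adam on a soft Dice loss
   `1 − mean_c (2Σpt + ε)/(Σp + Σt + ε)`, stratified patch sampling (80%
   of patches contain the ROI, 25% of those show aspiration, the remainder
   are glottis-free frames), online augmentation (rotation, zoom ≤ ×1.5,
   left-right mirror, contrast, brightness ±25% of the frame mean), and
   Jaccard-based early stopping: the state with the highest validation
   mean Jaccard is retained.
4. **Post-processing** — per-class thresholding, largest connected
   component for the glottis, and restriction of the other classes to that
   component: `mask_c ← mask_c ∧ LCC(mask_glottis)`.
5. **Evaluation** — Dice `2|X∩Y|/(|X|+|Y|)` and Jaccard `|X∩Y|/|X∪Y|`
   overlap scores; a frame-level confusion matrix for aspiration detection
   (a frame is a true positive when aspiration was segmented with Dice > 0
   against the reference), precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
   `F1 = 2TP/(2TP+FP+FN)`; the false-positive frame rate on glottis-free
   frames; and Spearman's ρ between reference bolus size and Dice.
6. **Timeline / XAI** — per-frame pixel counts per class, maximal runs of
   ≥ `min_consecutive` frames with ≥ `min_pixels` aspiration pixels (the
   meaningful frames), and an overlay video with per-class contours
   (yellow ROI, cyan cords, magenta aspiration; references dotted).

## Worked example

```python
import dataclasses
import numpy as np
from fees_xai import (
    SceneConfig, generate_video, PatchSampler, SamplerConfig,
    NetConfig, TrainConfig, build_net, train, predict_frame,
    compute_timeline, detect_event_runs,
)
from fees_xai.preprocess import downscale_frame, downscale_annotation

scene = SceneConfig(seed=100)           # 192×192, 200 frames, ~10 bolus events
pairs = []
for k in range(2):
    ds = generate_video(dataclasses.replace(scene, seed=scene.seed + k))
    pairs += list(zip(ds.frames, ds.annotations))
val = generate_video(dataclasses.replace(scene, seed=150))
val_pairs = [(downscale_frame(f), downscale_annotation(a))
             for f, a in list(zip(val.frames, val.annotations))[::5]]

sampler = PatchSampler(pairs, SamplerConfig(batch_size=8, patch_size=(96, 96)))
model = build_net(NetConfig(base_filters=8, depth=3), seed=100)
model, history = train(model, sampler, val_pairs,
                       TrainConfig(learning_rate=1e-3, batch_size=8,
                                   val_interval=50, max_iterations=2000, seed=100))

held_out = generate_video(dataclasses.replace(scene, seed=160))
timeline = compute_timeline(held_out.frames, model)
runs = detect_event_runs(timeline, min_consecutive=3, min_pixels=1)
print(history.best_iteration, [(r.start_frame, r.end_frame, r.peak_frame) for r in runs])
```

On this seed the run prints best iteration `1500` and eight detected runs,
e.g. `(49, 59, 52)` — frames 49–59 with the peak bolus at frame 52 — which
cover all seven ground-truth aspiration events of the held-out scene that
last at least three frames (the generator's event log lists
`(33, 43), (46, 61), (75, 82), (95, 98), (128, 130), (144, 151), (190, 197)`).
Held-out glottis segmentation reaches a median Dice of 0.98 and aspiration
0.91. The validation curves show the glottis and vocal cords learned within
a few hundred iterations while the aspiration class takes off only around
iteration 850 — the same ordering the clinical task exhibits, where the
anatomy is learned long before the rare, variable bolus class.

A command-line interface wraps the same workflows:

```bash
fees-xai synth --config cfg.yaml --out data/ --seed 5
fees-xai train --out models/unet --seed 5
fees-xai timeline --model models/unet --video data/synthetic-000005.tif --out report/
```

`timeline` writes `overlay.tif`, `timeline.csv`, `events.json` and
`timeline.png` (the pixel-count curves with a zoom panel around the
highest-peak event).

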