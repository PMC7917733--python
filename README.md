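# gaitstream

Two-stream action recognition for quadruped (felid) video clips:

- **Outline stream** — extracts the object contour from a per-frame binary
  mask, rasterizes it at 112×112, and classifies it with a small VGG-style
  CNN (three 3×3 conv blocks of 64/128/256 channels, each followed by a
  2×2 stride-2 max pool, then two fully-connected layers and softmax).
- **Skeleton stream** — computes the knee bending angle (law of cosines at
  the knee over the hip/knee/ankle triple) for the two visible legs in
  every frame, windows the normalized angle series, and classifies windows
  with an LSTM.
- **Fusion** — final clip score is the convex combination
  `y = w·y_outline + (1−w)·y_skeleton`, with `w` grid-searched on
  validation accuracy.

Classes: `standing` (0), `ambling` (1), `galloping` (2).

Because no public video dataset exists for this task, the package ships a
kinematic **synthetic-gait simulator**: an articulated 2-D stick quadruped
whose knee angles follow per-class sinusoidal regimes (standing confined
to ≈140–160°, galloping sweeping ≈80–180°, ambling intermediate), with
configurable tracking jitter and landmark dropout, plus silhouette-mask
rendering. The whole pipeline trains and evaluates on one CPU in minutes.

Both neural models run on a small numpy backend (`gaitstream/_nn.py`) —
no deep-learning framework is required.

## CLI

```bash
# end-to-end demo: simulate -> train both streams -> fuse -> evaluate
gaitstream demo --n-per-class 20 --seed 0

# step by step
gaitstream simulate --n-per-class 10 --seed 1 --out dataset.h5
gaitstream train-skeleton --data dataset.h5 --out skeleton_model.npz
gaitstream train-outline  --data dataset.h5 --out outline_model.npz
gaitstream predict --data dataset.h5 \
    --outline-model outline_model.npz --skeleton-model skeleton_model.npz \
    --out preds.json
gaitstream fuse --outline-preds preds.json --skeleton-preds preds.json \
    --weight 0.5 --out fused.json
gaitstream evaluate --preds fused.json
```

`simulate` writes an HDF5 clip bundle (`coords` (T×18×2), `visible`
(T×18), optional `masks` (T×H×W), attrs `label`/`fps`/`seed`), a keypoint
CSV mirror (`clip_id, frame_idx, x0, y0, v0, …, x17, y17, v17`), and a
train/test split manifest. Models save as `.npz` weights with a JSON
sidecar recording config, seed, and the training log.

## Keypoint conventions

18 landmarks per frame, image-pixel coordinates (origin top-left, y down).
The hind-leg knee triple defaults to 0-based indices (13, 14, 15)
(hip/knee/ankle) and the front-leg triple to (9, 10, 11); both are
configurable via `SkeletonSchema`. Non-visible landmarks carry NaN
coordinates and are excluded from angle computation; invalid frames are
filled by linear interpolation (edges copy the nearest valid value), and a
clip with >30% invalid frames on either leg is rejected.

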