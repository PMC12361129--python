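# axonfield

Distance-field-supervised segmentation of neuronal axons in 3D fluorescence
microscopy volumes, with the full surrounding toolchain: supervision-label
generation from SWC skeletons, a 3D U-Net regression network with a
region-weighted L1 loss, prediction-based image enhancement, skeleton-matching
evaluation metrics, and a synthetic phantom generator for controlled
experiments.

It is aimed at people building or benchmarking axon reconstruction pipelines
for whole-brain imaging (fMOST, light-sheet): thin, weakly labeled axons
whose signal can drop to near-background within a few microns, surrounded by
round and strip-shaped interfering structures.

## The method

Annotated centerlines (SWC) are converted into a regression target instead of
a binary mask.  With skeleton points `S = {s_0 … s_n}` (resampled to ≤ 1 voxel
spacing), the label support is the union of open 3-voxel balls

    S_reg = { v : min_i ‖v − s_i‖ < 3 }

and each in-region voxel `p` gets the value

    disf(p) = exp( −dist(p, S) / 2σ² ),   σ = 2 voxels by default,

where `dist(p, S)` is the perpendicular distance from `p` to the local
centerline direction at its nearest skeleton point.  The field is 1 on the
centerline and decays outward.

A 3D U-Net (encoder channels doubling 16 → 512 at full scale; additive
residual skip connections; stride-2 transposed-convolution upsampling)
regresses this field from the raw volume, trained with Adam (lr 2·10⁻⁴,
batch 1) under a four-term L1 loss

    L = 1/N ‖y_p − y_g‖₁ + 1/#reg1 ‖(y_p − y_g)_reg1‖₁
      + 1/#reg2 ‖(y_p − y_g)_reg2‖₁ + 1/#reg2* ‖(y_p − y_g)_reg2*‖₁

with `reg1 = {y_g > 3/255}`, `reg2 = {y_g > 103/255}` and
`reg2* = {x > 103/255}` (bright voxels of the *input*).  Per-region
normalization makes rare foreground voxels dominate the gradient — the
mechanism that recovers very weak axonal segments.

Predictions are used two ways: thresholded and skeletonized directly, or
overlaid onto the raw image (`clip(raw + 255·y_p, 0, 255)`) to boost contrast
before running a conventional tracer.  Skeletons are compared by
recall/precision/F1 under a strict 3-voxel Euclidean matching threshold, and
topologically by the Aggregated Jaccard Index over instance maps built from
per-skeleton region expansion.

The network stack (3D convolutions with hand-written backward passes, Adam)
is implemented in numpy and runs on a single CPU at the problem sizes used
here; it is validated against finite-difference gradient checks.

## Worked example

```python
import numpy as np
from axonfield import (SynthConfig, generate_volume, characterize_volume,
                       resample_skeleton, make_distance_field, skeleton_scores,
                       extract_foreground, enhance)

cfg = SynthConfig(shape=(64, 64, 64), n_axons=(2, 2), snr_target=4.0,
                  weak_segment_fraction=0.5, seed=7)
vol, trees = generate_volume(cfg)
stats = characterize_volume(vol, trees, block_size=64)
print(f"volume SNR {stats.snr_mean:.2f}, skeleton density {stats.density_mean:.5f}")

rs = [resample_skeleton(t) for t in trees]
field = make_distance_field(rs, vol.shape)
print(f"label support: {(field > 0).sum()} voxels, peak {field.max():.1f}")

G = np.concatenate([t.positions() for t in rs])
thr = 103 / 255
r_raw = skeleton_scores(extract_foreground(vol.data, thr), G)[0]
r_enh = skeleton_scores(extract_foreground(enhance(vol, field).data, thr), G)[0]
print(f"skeleton recall at threshold 103/255: raw {r_raw:.3f} -> enhanced {r_enh:.3f}")
```

Output:

```
volume SNR 4.05, skeleton density 0.00083
label support: 4556 voxels, peak 1.0
skeleton recall at threshold 103/255: raw 0.594 -> enhanced 1.000
```

The two synthetic axons render half their segments at near-background
intensity; plain thresholding finds 59 % of the centerline points, while the
same threshold after overlaying the ×255-scaled distance field finds all of
them — the enhancement effect the method is built around.

## Command line

Every step is also a subcommand of the `axonfield` CLI:

```
axonfield simulate --out data/ --n 10 --shape 64,64,64 --seed 0
axonfield make-labels --swc data/vol_000.swc --shape 64,64,64 --out label.tif
axonfield train --config train.yaml
axonfield predict --model run/model.npz --in vol.tif --out pred.tif
axonfield enhance --in vol.tif --pred pred.tif --out enhanced.tif
axonfield skeletonize --in pred.tif --threshold 0.5 --out skel.swc
axonfield evaluate --pred skel.swc --truth truth.swc --shape 64,64,64 --out report.json
axonfield bootstrap --config boot.yaml --rounds 2
```

`bootstrap` runs the iterative annotation loop (train → predict a pool →
skeletonize → optional manual revision via `--revision-dir` → regenerate
labels → retrain).  Each command writes a JSON summary next to its outputs.

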