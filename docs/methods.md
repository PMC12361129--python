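# Methods

## Problem setting

Long-range axons in whole-brain fluorescence volumes (fMOST and similar
modalities) are thin, weakly labeled, and embedded in backgrounds containing
bright non-axonal structures.  Automatic tracers miss weak segments; manual
tracing is the bottleneck of projection mapping.  The approach implemented
here regresses a *distance field* — a voxel map that peaks on the axonal
centerline and decays outward — with a 3D U-Net, then uses the predicted
field either directly (skeletonize its foreground) or as a contrast
enhancer (overlay the ×255-scaled field on the raw image before running a
conventional tracer).

## Supervision labels

Given an annotated skeleton `S = {s_0 … s_n}` (SWC, voxel units):

1. **Resampling.** Nodes are linearly interpolated along each edge so
   adjacent points are ≤ 1 voxel apart.  Original nodes are never moved.
2. **Region expansion.** The label support is
   `S_reg = {v : min_i ‖v − s_i‖ < 3}` — the union of open 3-voxel balls
   around all skeleton points.  The inequality is strict; a single isolated
   point therefore covers exactly the 93 lattice sites with squared
   distance ≤ 8.
3. **Distance field.** For an in-region voxel `p`, with `s(p)` its nearest
   skeleton point and `u` the unit direction from `s(p)` toward its
   successor, the perpendicular centerline distance is
   `d(p) = ‖(p − s(p)) × u‖` (the component of `p − s(p)` normal to the
   local direction).  The label is `exp(−d / (2σ²))`, 1 on the centerline,
   0 outside `S_reg`.

Numerical choices for degenerate geometry: a point coinciding with a
skeleton node has distance 0; a single-node skeleton has no direction and
falls back to the Euclidean distance; a leaf node reuses its incoming
(parent) direction; at a branch node the segment yielding the smaller
perpendicular distance wins, with ties resolved toward the lowest child id.
Overlapping fields from different trees combine by voxel-wise maximum.
Nearest-point queries run through a k-d tree and are tested for equality
against a brute-force scan.

Two deliberate parameter decisions:

* **σ (default 2.0 voxels).** The decay rate is exposed in `LabelConfig`;
  2.0 puts the field at ≈ 0.47 at the region boundary (d = 3), which keeps a
  usable gradient across the whole support.
* **Linear, not squared, exponent.** The default decay is
  `exp(−d/(2σ²))` rather than the conventional Gaussian `exp(−d²/(2σ²))`;
  a `squared_exponent` switch selects the Gaussian.  Fields differ only in
  their radial profile; both peak at 1 on the centerline.

## Network and training

The regression network is a 3D U-Net: `levels` encoder blocks with channels
doubling from `base_channels` (capped at 512), 2× max-pool downsampling,
a mirrored decoder with stride-2 transposed convolutions, and additive
(residual) skip connections between matching scales (a concatenation mode
exists behind a flag).  Each block is two 3×3×3 convolutions with LeakyReLU
(slope 0.1).  Blocks carry **no data-dependent normalization by default**:
instance normalization is available (`norm="instance"`) but makes tiled and
untiled inference differ, because tile statistics differ from volume
statistics; the default configuration keeps them identical wherever the
tile margin exceeds the receptive-field radius.  The single-channel head is
linear, clamped to [0, 1]; during training the clamp passes gradients
straight through so saturated voxels continue to learn.

The full-scale profile is 6 levels with channels 16 → 512; the CPU-sized
toy profile used in all synthetic experiments is 3 levels, 8 → 32.

Training minimizes a four-term region-weighted L1 loss between prediction
`y_p` and label `y_g` given input image `x`:

    L = mean|y_p − y_g|                       (all voxels)
      + mean over {y_g > 3/255}  |y_p − y_g|  (any labeled foreground)
      + mean over {y_g > 103/255}|y_p − y_g|  (near-centerline foreground)
      + mean over {x  > 103/255} |y_p − y_g|  (bright image structures)

Each term is normalized by its own region size; an empty region contributes
zero.  Sparse foreground voxels therefore carry orders of magnitude more
weight than background, which is what drives detection of very weak
segments; the fourth term forces a decision (axon or not) on bright
structures regardless of their label.

Optimization is Adam at learning rate 2·10⁻⁴ with batch size 1.  The whole
layer stack (3D convolutions, transposed convolutions, pooling, the loss
gradient) is implemented in numpy with hand-written backward passes,
validated against finite differences in float64; Adam and the training loop
sit on top.  One integer seed controls the train/validation split
(fractions 0.79/0.10/0.11, mirroring a 676/85/91 split), weight
initialization (He), crop sampling, and data order.  Training runs on
random 32³ crops (4 per volume per epoch), biased 70 % toward crops centered
on labeled foreground; the best-validation checkpoint is kept.

Inference is tiled: tiles of 64³ with an overlap margin, only tile
interiors written back.  A margin larger than the receptive-field radius
(≈ 22 voxels for the toy profile) makes tiled output exactly match untiled
output; smaller margins trade exactness for speed.  Inputs are
reflect-padded to a multiple of `2^(levels−1)` and cropped back, so output
shape always equals input shape.

## Enhancement and skeleton extraction

Enhancement adds the ×255-scaled predicted field to the raw 8-bit image and
clips: `clip(raw + 255·y_p, 0, 255)`.  A zero field is the identity.

Foreground extraction returns voxels with field value above a threshold
(default 0.5).  The bundled skeletonizer is a deliberately simple fallback:
a Euclidean minimum spanning tree over the foreground points (edges above a
2-voxel cutoff split components), followed by pruning of side branches
shorter than 4 voxels that hang off junctions.  It preserves unbranched
paths exactly and never consumes a component without a junction.  Any
external skeletonizer producing SWC trees can be plugged in instead; the
dedicated point-cloud methods used in production pipelines substantially
outperform the fallback, particularly in precision.

## Evaluation metrics

With `P` the predicted and `G` the reference skeleton point set (both at
≤ 1-voxel spacing), a point matches when its nearest counterpart lies
strictly within `Thre = 3` voxels (Euclidean).  Recall is the matched
fraction of `G`, precision the matched fraction of `P`, F1 their harmonic
mean.  The threshold matches the 3-voxel label expansion radius.  The
distance is the plain 2-norm; a `squared_norm` flag compares the squared
distance against the same threshold for compatibility with that
alternative reading.  Conventions: both sets empty scores perfect; an empty
reference side leaves the corresponding score undefined (NaN with a
warning).

For topology, every connected skeleton's radius-3 expanded region forms one
instance (contested voxels go to the nearer skeleton, ties to the lower
id).  The Aggregated Jaccard Index pairs each reference instance greedily
(ascending id) with the unused predicted instance of largest Jaccard index
— ties to the lowest id, zero-overlap instances stay unmatched — and scores
matched intersections over matched unions plus all unmatched instance
sizes.  Implementations of both metric families are tested against
exhaustive brute-force oracles.

## Synthetic phantoms

The generator emulates the documented diversity of real axon blocks, not
their physics:

* **Geometry.** Axons are persistent random walks (step 0.8 voxels,
  bounded curvature, reflected at the walls), optionally with one branch,
  rendered as tubes with a Gaussian radial profile (radius 1–3 voxels).
  Ground truth is returned as SWC trees at the walk's native ≤ 1-voxel
  spacing.
* **Intensity.** Per-segment (20-node) intensities are drawn from a strong
  range (100–255 on the 8-bit scale) or, with probability 0.3, a weak range
  (8–30) barely above background — emulating sparsely labeled stretches.
  Background is Gaussian (mean 12, std 6).
* **Distractors.** Round blobs and short strip-shaped tubes (the two
  documented interference morphologies) are rendered without ground-truth
  skeletons, providing false-positive bait.
* **SNR targeting.** When a per-volume SNR target is set, tube intensities
  are rescaled toward it (contrast-to-noise definition below), saturating
  at 255; if saturation leaves the target short, background fluctuations
  (noise and distractors jointly) are damped instead — mirroring the fact
  that high-SNR acquisitions have proportionally quieter backgrounds.  A
  target that would need background noise under 0.5 grey levels, or that
  still falls short of 60 % of the target after these adjustments, raises a
  configuration error.  The benchmark corpus spans targets 3–12 evenly.

What the phantoms do **not** model: the fMOST point-spread function and its
axial anisotropy, stitching artifacts, vasculature, dendrites and somata,
and intensity gradients across a volume.  Passing tests on phantoms
demonstrates that the pipeline's machinery (labels, loss, optimization,
metrics) behaves as specified and that field supervision detects weak
tubular signal in noise; it does not certify performance on real brain
volumes.

Characterization follows the per-sub-block protocol: volumes are
partitioned into 64³ sub-blocks; each reports SNR, skeleton density, and
skeleton-point intensity, aggregated to a volume mean and standard
deviation.  SNR uses the contrast-to-noise form
`(mean signal − mean background) / std background`, with signal voxels the
radius-3 expanded region and background its complement (so distractors
count as background).  Density is skeleton points per sub-block voxel.
Both estimator choices are configurable, since no canonical definitions
exist for these quantities.

Block selection reduces a corpus to `k` representatives by K-means over
normalized 256-bin grayscale histograms, keeping the volume nearest each
centroid.

## The scaled-down benchmark

`axonfield.experiments.run_benchmark` fixes the problem sizes of the
end-to-end study: 30 volumes of 64³ (SNR targets 3–12, weak segments,
blob and strip distractors), 25 for training, 5 held out; toy-profile
network, 8 epochs of Adam 2·10⁻⁴ on 32³ crops.  Held-out volumes are scored
by skeleton recall/precision/F1 of the thresholded predicted field (0.5)
against the resampled ground truth, plus AJI of instance maps built from
MST-skeletonized predictions.  The baseline is Otsu-threshold foreground
extraction on the raw volumes.  `enhancement_gain` isolates the
enhancement property on one all-weak-signal volume: fixed-threshold
(103/255) extraction on the raw versus the ground-truth-field-enhanced
volume.

On these phantoms the trained network typically saturates recall while the
raw-intensity baseline misses weak segments; precision is substantially
lower than recall because the predicted field (deliberately) covers a
3-voxel tube around each centerline and flags strip distractors — the same
high-recall/moderate-precision signature the full-scale method exhibits.
The AJI of the fallback-skeletonized predictions is low; turning a
foreground cloud into well-separated instances is precisely the job of the
dedicated point-cloud skeletonizers the interface leaves pluggable.

## Known limitations

* The numpy network stack is CPU-bound and single-threaded beyond BLAS;
  full-scale (6-level, 192³, 852-volume) training is out of its reach by
  design.  The architecture, loss and protocol are size-independent.
* The fallback MST skeletonizer keeps every foreground voxel as a node; it
  is a correctness-tested placeholder, not a competitive tracer.
* Anisotropic voxels are not modeled anywhere; coordinates are isotropic
  voxel units.
* `expand_region` stamps per-point windows, which is exact but scales with
  skeleton length; very dense 192³ scenes take seconds, not milliseconds.
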