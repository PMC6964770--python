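# dualpath3d

Patch-based volumetric segmentation of liver and liver tumors in abdominal
CT, built around a **dual-path multiscale 3D convolutional network** with
**dense-CRF refinement** and a full volumetric evaluation suite. The package
is aimed at medical-image-analysis researchers who want a complete, inspectable,
CPU-runnable implementation of this family of pipeline — including a synthetic
CT phantom generator, so every stage is testable end to end without clinical
data.

## The method

CT volumes are Gaussian-smoothed slice-wise (σ = 1), z-scored against the
whole image, and optionally subsampled in-plane. Training examples are
co-centred **dual-scale patch pairs**: a fine local cube of edge *L* (default
43 voxels) and a coarse global cube covering *3L* (129) voxels, block-mean
downsampled to the same edge — same grid, three times the anatomical context.

Each patch feeds one of two identical paths of eight blocks
(3×3×3 convolution → batch norm → PReLU, no pooling), with identity residual
additions between blocks 2→4, 4→6, and 6→8. The receptive field of a path
follows the recursion

    R_l = R_{l-1} + (k_l − 1) · Π_{i<l} s_i ,  R_0 = 1,

which gives a 17×17×17 field after eight unit-stride 3³ layers — the minimum
meaningful patch edge. Path outputs are fused by voxel-wise addition and
passed through 1×1×1 "fully connected" convolution stages (spatial structure
preserved) to a softmax over {background, liver, tumor}. Training minimizes
per-voxel cross-entropy with L1/L2 kernel penalties under RMSProp with
momentum (lr 0.001, decay 0.9, momentum 0.6, ε 1e-4, dropout 0.5, batch 10).
The network — forward pass, exact backpropagation, and the optimizer — is
implemented directly in NumPy.

Whole-volume probability maps (tiled, overlap-averaged) are refined by a
**fully connected CRF** whose pairwise energy couples every voxel pair through
appearance (position + intensity) and smoothness (position) Gaussian kernels
with Potts label compatibility, solved by parallel mean field — exactly on
small volumes, via Gaussian-filtering message approximation (bilateral grid)
on full volumes. Segmentations are scored with Dice, sensitivity,
specificity, Hausdorff distance, and average symmetric surface distance
(ASSD).

## Worked example

```python
import numpy as np
import dualpath3d as d
from dualpath3d.network import DualPathNetwork, NetworkConfig
from dualpath3d.training import TrainConfig, train, predict_volume

# 1. synthetic CT phantoms with exact ground truth
pairs = []
for i in range(20):
    vol, lab = d.generate_phantom(d.PhantomSpec(seed=1000 + i, tumor_count_range=(1, 4)))
    vol = d.preprocess(vol)                       # smooth + z-score
    centers = d.sample_training_centers(lab, 6, seed=77 + i)
    pairs += [d.extract_dual_patch(vol, lab, c, edge=19) for c in centers]

# 2. miniature dual-path network (2 blocks/path, 8 feature maps)
cfg = NetworkConfig(n_blocks_per_path=2, feature_maps=(8, 8),
                    residual_pairs=((1, 2),), fc_widths=(16,), seed=1)
net = DualPathNetwork(cfg)
trace = train(net, pairs, TrainConfig(epochs=50, batch_size=10, seed=1))
print(f"loss: {trace[0]:.3f} -> {trace[-1]:.3f}")

# 3. segment a held-out phantom and score it
vol, lab = d.generate_phantom(d.PhantomSpec(seed=1100, tumor_count_range=(1, 4)))
maps = predict_volume(net, d.preprocess(vol), tile_stride=19, edge=19)
pred = maps.argmax_labels()
print("liver Dice:", round(d.dice(d.confusion(pred, lab.data, d.LIVER)), 3))
```

Output from this exact script:

```
loss: 1.398 -> 0.092
liver Dice: 0.967
```

The loss trace shows the cross-entropy falling from near-chance (ln 3 ≈ 1.1
plus regularization) to a confident fit; a liver Dice of 0.967 on an unseen
phantom means the predicted liver mask overlaps the true one almost
completely. CRF refinement of a segmentation is one call:

```python
from dualpath3d import refine, probs_from_labels
labels, marginals = refine(probs_from_labels(pred_labels), image)
```

A command-line interface mirrors the library:

```bash
dualpath3d phantom --seed 7 --out ph/
dualpath3d preprocess --sigma 1 --kernel-width 3 --subsample 2 --in ph/volume.nii.gz --out pre.nii.gz
dualpath3d evaluate --pred pred.nii.gz --truth ph/labels.nii.gz --classes liver,tumor
```

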