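# Methods

This note documents the models, numerical choices, and calibrations behind
`dualpath3d`, and what the synthetic-phantom experiments do and do not show.

## Preprocessing

Smoothing uses the 2D Gaussian H(i,j) ∝ exp(−(i²+j²)/2σ²) evaluated on
integer offsets of a square window (default σ = 1, width 3) and explicitly
normalized to sum to one — an unnormalized kernel would rescale intensities.
Filtering is applied slice-by-slice in the axial plane by default, matching
the 2D form of the kernel; a separable 3D mode is available
(`mode="3d"`). Boundaries use mirror padding, which avoids edge darkening.
Normalization is a whole-image z-score; in-plane subsampling is block-mean
(anti-aliasing) with a nearest-neighbour option. The pipeline order is
smooth → normalize → subsample by default and is configurable; the
operations commute in rank order, so the choice mainly affects the intensity
scale seen by later stages. Augmentation (rotate90 / flip / crop / scale)
applies one geometric transform jointly to image and labels, with linear
interpolation for intensities and nearest-neighbour for labels, fully
deterministic under a seed.

## Dual-scale patch sampling

The receptive-field recursion R_l = R_{l−1} + (k_l − 1)·Π_{i<l} s_i (R_0 = 1)
is computed per axis; the dependency-tracing oracle in the tests confirms it
measures an *extent* — strided unit kernels leave gaps inside the span. The
global patch is cut as a factor·edge cube (129 for edge 43, factor 3) and
block-mean downsampled by the factor; out-of-bounds regions are padded with
the volume minimum, an air-like value. Training centers are stratified by
class with exact largest-remainder allocation — with tumors occupying well
under 1% of voxels, unstratified sampling would effectively never present a
tumor voxel to a desk-scale run. Both random (seeded) and dense-grid center
generation are provided.

## Network

Each path is a chain of conv(3³, zero-padded "same") → batch norm → PReLU
blocks; convolutions carry no bias (batch norm's shift makes it redundant).
"Same" padding keeps path outputs voxel-aligned 1:1 with the label patch; a
"valid" mode exists for central-region prediction. The published per-layer
table lists four conv entries (feature maps 30, 30, 40, 40) for eight
blocks; these are interpreted as consecutive pairs (blocks 1–2: 30, 3–4: 30,
5–6: 40, 7–8: 40), which matches the residual pairing structure 2→4, 4→6,
6→8. Residual additions are identity shortcuts; the 30→40 channel increase
at the 4→6 junction is reconciled by zero-padding the skipped tensor's
channels (parameter-free). The source of a residual pair is the tensor
flowing forward (i.e. post-addition where pairs chain). Path outputs are
fused by voxel-wise addition *before* the head — the coarse path's features
are not upsampled, following the literal fuse-by-addition description; the
head is two 1×1×1 stages of width 150 with PReLU and dropout, then a 1×1×1
classifier and softmax. Head widths are not dictated by the architecture and
are config-exposed. PReLU slopes initialize to 0.25; batch norm uses
ε = 1e−5 and running-average momentum 0.9. Setting `dual_path=False` gives
the single-path ("local only") ablation; `fm_multiplier=2.0` doubles every
width for the parameter-matched variant.

The whole network is implemented in NumPy. Convolutions run as a single
GEMM over an offset-major im2col matrix, cached between the forward and
backward pass; backpropagation is exact and is checked against central
finite differences in the tests. One caveat of that check: where the true
gradient is exactly zero (a conv bias feeding batch norm) or tiny, float32
forward noise dominates the difference quotient, so the comparison uses a
relative criterion with a small absolute floor.

## Training

The loss is the per-voxel mean cross-entropy (averaged over all voxels of
the batch, not per patch) plus L1 and L2 penalties on convolution kernels
only — biases, batch-norm affine parameters, and PReLU slopes are not
penalized. The optimizer is RMSProp with momentum,

    sq ← d·sq + (1−d)·g²;  mom ← m·mom + lr·g/√(sq+ε);  w ← w − mom,

with defaults lr 0.001, d 0.9, m 0.6, ε 1e−4, dropout 0.5 (fully connected
stages only), batch size 10, constant learning rate (an optional step decay
is config-exposed). Training is deterministic under a seed: batch shuffling
and dropout masks derive from it. A non-finite loss raises a training error
with diagnostics rather than continuing silently.

Whole-volume inference tiles the volume with dual-scale patches (default
stride 9) and averages overlapping softmax outputs; averaging points on the
probability simplex keeps per-voxel sums at 1.

## Dense CRF

The energy is E(x) = Σ_i U_i(x_i) + Σ_{i<j} [x_i ≠ x_j]·k(f_i, f_j), with
unaries U = −log(max(P, 1e−10)) from the network's probability maps and the
two-component Gaussian kernel

    k(f_i,f_j) = w1·exp(−‖Δp‖²/2θα² − ΔI²/2θβ²) + w2·exp(−‖Δp‖²/2θγ²).

Label compatibility is exact 0/1 Potts. Positions are in voxels, intensity
is the z-scored image value. The partition function is never computed; only
energy differences matter. Inference is parallel mean field for a fixed
iteration count, initialized from the softmax of the negated unaries; with
Potts compatibility the update simplifies to Q ← softmax(−U + K·Q).

Two message-passing routes share this update. On volumes ≤ 10⁴ voxels the
N×N kernel matrix is materialized (exact messages, zero diagonal). On full
volumes messages are approximated by Gaussian filtering: the smoothness
component by a spatial Gaussian filter rescaled by the kernel's lattice mass
(converting the normalized filter back to the unnormalized sum the energy
uses), the appearance component by a 4D bilateral grid (position/θα,
intensity/θβ, unit-rate sampling, σ = 1 blur) — the standard fast-bilateral
construction. Binning makes voxels in the same grid cell share messages;
this is the approximation's main artifact and is invisible at the default
bandwidths.

**Default parameters** (w1 = 0.02, w2 = 0.04, θα = 2, θβ = 0.5, θγ = 1.5,
5 iterations; unary confidence 0.9 when refining hard labels) were
calibrated once on phantoms with two requirements: isolated wrong-label
voxels must be flipped by their surroundings, and genuine small lesions —
a few hundred voxels at ~0.5 SD intensity contrast — must survive. The two
requirements bound the pairwise weight from both sides: per-voxel message
mass scales with the kernel's lattice mass (≈ (2π)^{3/2}θ³ per component),
and once w·mass exceeds a few units of unary energy, lesion boundaries erode
and the smallest lesions vanish entirely; below ~1 unit, speckles stop
flipping. A wide spatial bandwidth (θα ≳ 10) cannot satisfy both at any
weight, because a small lesion's neighbourhood is then dominated by
surrounding liver at near-equal intensity similarity.

**Known limitation.** Mean field is a local fixed-point method. On
enumerable instances whose unaries are near-uniform and whose dense
couplings are comparable to the unary gaps (a frustrated Potts regime), the
MAP labeling attains the exact energy minimum only ~60–75% of the time, and
asynchronous updates do not help. On structured instances that model the
refinement task — piecewise-constant truth, confident but partly corrupted
classifier unaries, label-correlated intensities — it attains the exact
minimum on ≥ 90% of instances, which is the regime the test suite pins.

## Evaluation metrics

Dice = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
Degenerate cases are explicit: Dice of two empty sets is 1.0, undefined
ratios return NaN with a logged warning, and distance metrics on an empty
set raise — phantoms with zero lesions are legitimate inputs. Hausdorff and
ASSD operate on *all* foreground voxels by default (a surface-voxel mode is
available) in voxel units (mm via spacing). The standard ASSD pools the
nearest-neighbour distances of both directions and divides by N1+N2; a
"literal" variant that divides the two already-averaged directed distances
by N1+N2 — a double normalization that appears in some write-ups — is kept
behind a flag for comparison, never as the default.

## Synthetic phantoms

A phantom is an off-center liver ellipsoid (HU 120) on soft-tissue
background (HU −60) with an adjacent organ ellipsoid at liver-like HU —
reproducing the classic difficulty that neighbouring organs match the liver
in CT value — plus 0–6 spheroidal lesions and additive Gaussian noise
(SD 10 HU, a realistic contrast-CT noise level). Lesion volumes are uniform
on 38–349 mm³; the lesion–liver contrast is drawn from a normal with mean
31.94 HU and SD 20 truncated to [0, 98] (the truncation raises the
realized mean to ≈ 34.3; the tests validate moments against the exact
truncated distribution). Rasterization nudges each spheroid's scale so its
voxel count stays inside the volume range; lesions are placed with exact
Euclidean clearance inside the liver and do not overlap. The default grid
is 96³ at 1 mm isotropic spacing — full clinical geometry (512×512×~500,
anisotropic) exercises no additional code path. Speckle injection flips
isolated voxels to a wrong label at least 3 voxels from any same-label
structure (including earlier speckles) and 3 voxels from the volume border;
border voxels of a finite dense CRF receive a fraction of the interior
pairwise vote mass and are not reliably correctable at lesion-preserving
weights.

What the phantoms do **not** emulate: anatomical shape variability, vessels
and ducts, partial-volume effects at real slice thickness, beam hardening
and motion artifacts, and contrast-phase differences. Passing the phantom
suite therefore demonstrates that the pipeline's machinery is correct and
that its qualitative mechanisms (multiscale fusion helping over a single
path, CRF removing scattered errors) operate as described — not that the
miniature networks would reach clinical benchmark accuracy.

## Desk-scale experiment sizes

The end-to-end run in the test suite uses a miniature configuration chosen
as the smallest that exercises every mechanism: 2 blocks per path, 8 feature
maps, one residual pair, patch edge 19 (comfortably above the 2-block
receptive field of 5), 20 training phantoms × 6 class-balanced patches, 50
epochs, 5 held-out phantoms. Training phantoms are constrained to ≥ 1 lesion
so three-class balanced sampling is well defined. Under these conditions the
dual-path network reaches mean liver Dice ≈ 0.96 held-out, and its final
training loss is at or below the matched single-path network's, the expected
qualitative ordering.
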