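# Methods

This note documents the models, numerical choices and limitations behind
`munet`, a desk-scale implementation of a selective-scan state-space
(Mamba-style) U-Net for multimodal brain-tumor segmentation, together with
its composite training loss, evaluation metrics, BraTS-convention data
handling and a synthetic phantom generator.

## Tensor engine

The network, losses and optimizer run on the package's own reverse-mode
automatic-differentiation engine over NumPy arrays (`munet.autodiff`,
`munet.nn`). It is a tape-based design with a deliberately small operator
set: elementwise arithmetic and nonlinearities, matmul, reductions, shape
ops, an im2col-based 2-D convolution (stride/dilation/groups) and the
sequential state-space scan, whose adjoint recurrence is hand-written so
graph size is independent of sequence length. All arithmetic is float64;
every operator's gradient is checked against central differences in the
test suite. Computation is deterministic: a fixed seed and input produce
bit-identical parameters and logits across runs on one machine.

## State-space core

A linear state-space model h'(t) = A h(t) + B x(t), y(t) = C h(t) is
discretized with a zero-order hold over a time scale Δ:

    Ā = exp(ΔA),    B̄ = (ΔA)^{-1} (exp(ΔA) − I) ΔB.

`discretize_zoh` computes B̄ from the augmented matrix exponential
exp([[ΔA, ΔB], [0, 0]]), which equals the integral form exactly and remains
finite for singular ΔA, so B̄ → ΔB as A → 0. For fixed parameters the
recurrence h_t = Ā h_{t−1} + B̄ x_t is equivalent to a causal convolution
with kernel K = [CB̄, CĀB̄, …, CĀ^{M−1}B̄]; the kernel path is kept for
verification only, because the *selective* scan below varies Δ, B, C per
step, which a fixed kernel cannot represent. (Some presentations write the
kernel with the undiscretized B; this implementation uses B̄ throughout for
consistency with the recurrence.)

**Selective scan (S6).** Per channel, A is diagonal with learnable real
entries initialised to −(1, 2, …, N); N = 8 states by default. The step
size Δ (per channel, made positive by a softplus), the input map B and the
output map C (per step, shared across channels) are linear projections of
the input sequence, so the recurrence is content-dependent. Discretization
is elementwise-exact ZOH: ā = exp(Δa), b̄x = φ(Δa)·Δ·b·x with
φ(z) = (e^z − 1)/z evaluated by a short Taylor series below |z| = 1e−5.
With the input projections zeroed the layer reduces exactly to the plain
discrete SSM, which the tests exploit as an oracle.

**SS2D.** A C×H×W feature map is expanded into four directional sequences
— (1) row-major, (2) its reversal, (3) column-major, (4) its reversal —
each a permutation of the map's entries. Each sequence is processed by the
selective scan and the four results are realigned and summed ("merge"), so
an identity scan reproduces 4z exactly; a learned 1×1 projection follows
the merge. The scan parameters are shared across the four directions and
the directions are stacked into the batch axis, which keeps the model
compact and runs one scan loop instead of four.

## SD-Conv and the SD-SSM block

SD-Conv chains a spatial reconstruction unit (SRU), a channel
reconstruction unit (CRU) and a depthwise-separable convolution. The SRU
ranks channels by their group-norm scales (γ²/Σγ², with a small epsilon so
γ = 0 yields a uniform 0.5 gate), gates the map through a sigmoid with
threshold 0.5 into informative / less-informative streams, and cross-adds
the two half-channel groups. The CRU splits channels (ratio 0.5), squeezes
each part by 2 with 1×1 convolutions, transforms the upper part with a
group conv + pointwise conv and the lower part with a pointwise conv +
passthrough, and merges the two branches with softmax attention over their
global-average pooled responses. All convolutions inside the unit are
bias-free. The parameter count of SD-Conv at C channels is ≈ 2.8·C² + O(C),
strictly below the 9·C² of a standard 3×3 convolution for C ≥ 16.

An SD-SSM block runs two branches over the stage feature map: X1 =
batch-norm → stacked SD-Convs at dilation rates (1, 2, 4); X2 = channel
layer-norm → 1×1 linear → SiLU → SD-Conv → SS2D. Both branch outputs are
multiplied by learnable scalars initialised to zero and added to the input
as a residual, so a freshly constructed block is exactly the identity —
this stabilises early training and gives the tests an exact residual
identity to assert.

## MUNet

Patch embedding is a stride-p convolution (non-overlapping p×p patches,
linear projection to the embedding width). Each encoder stage applies
`depths` SD-SSM blocks and a patch merge (2×2 concatenation + linear
reduction: half resolution, double channels); the deepest stage acts as the
bottleneck. The decoder mirrors with patch expansion (1×1 expansion +
pixel shuffle), additive skip fusion (decoder + encoder features, then a
1×1 projection — addition chosen over concatenation to keep stage widths
symmetric), and SD-SSM blocks. A final expansion restores full resolution
and a 1×1 head produces per-class logits. Volumes are segmented
slice-by-slice along the last (axial) axis; the architecture is 2-D
throughout.

Defaults: 4 input modalities, 4 classes, 3 stages, embedding width 32,
2 blocks per stage, patch size 4, 8 scan states. The desk-scale
configuration used by the mechanism tests is embedding width 16 with
2 stages, patch size 2, 4 scan states and dilation rates (1, 2). The
smaller patch matters for fidelity, not just cost: it keeps the embedding
of a 2×2×4 patch lossless (16 numbers into 16 dims), which a run must have
to reproduce thin structures like the enhancing rim with pixel accuracy;
the reduced state size and dilation stack keep the 300-step training run in
the minutes range on one CPU.

## Composite loss

* **Soft mIoU**: 1 − mean over classes of (ΣPG + ε)/(Σ(P+G−PG) + ε),
  ε = 1e−6. The averaging index runs over classes (one IoU per class);
  an absent class contributes ε/ε = 1, i.e. it is not penalised.
* **Soft Dice**: 1 − (2ΣPG + ε)/(ΣP² + ΣG² + ε), accumulated over all
  classes and pixels as one global ratio.
* **Boundary**: per class with non-empty ground truth, predicted
  probability mass is weighted by the Euclidean distance transform φ to
  the ground-truth region (zero inside it) and averaged over the outer
  boundary band {0 < φ ≤ w}, w = 5 px by default. The band does two jobs:
  it realises the "boundary region" over which boundary error is assessed,
  and it keeps the term on the same O(1) scale as the overlap losses —
  normalising instead by the boundary-pixel count makes the term orders of
  magnitude larger for small structures and visibly collapses training.
  The surrogate is linear in P and exactly zero for a perfect prediction.
  The exact evaluation form (symmetric mean nearest-neighbour distance
  between hard-mask boundaries) is exposed separately for reporting.

Total loss = α·mIoU + β·Dice + γ·Boundary with α = β = γ = 1 by default.

## Metrics

Kappa, DSC, IoU, sensitivity, precision, specificity, accuracy and
balanced accuracy are computed from exact integer confusion counts;
degenerate denominators are reported as undefined (None), never as zero.
A pair of empty masks scores DSC = IoU = 1 with an undefined Hausdorff
distance, matching common BraTS tooling. Boundaries are foreground pixels
with a background face-neighbour (4-connectivity in 2-D, the image border
counting as background). Hausdorff95 is the symmetric 95th percentile of
nearest-neighbour boundary distances with NumPy's linear-interpolation
percentile convention, in isotropic pixel units (no voxel-spacing
scaling). Every metric is cross-checked against an independent brute-force
implementation on hundreds of random mask pairs.

## Data and the phantom generator

Cases follow the BraTS layout: one directory per case with `_t1`, `_t1ce`,
`_t2`, `_flair` (and optional `_seg`) NIfTI volumes sharing one affine.
Labels use the BraTS set {0, 1, 2, 4} (1 necrotic core, 2 edema,
4 enhancing tumor) and the evaluation regions are ET = {4}, TC = {1, 4},
WT = {1, 2, 4}, nested by construction. Modalities are z-scored over
nonzero voxels before slicing; zero background is preserved.

The phantom generator renders nested ellipsoidal lesions inside an
ellipsoidal brain mask: necrotic interior (label 1) up to the enhancing
radius, enhancing rim (label 4) up to the core radius, edema halo
(label 2) up to the edema radius — so region nesting holds for every
generated case. Four modality channels are rendered from a
tissue-contrast table (edema bright on T2/FLAIR, enhancing rim bright on
T1c, necrosis dark on T1/T1c), multiplied by a smooth random second-order
polynomial bias field (amplitude 0.2) and perturbed with Gaussian noise
(σ = 5 on a base intensity of 100). Defaults produce BraTS-shaped
240×240×155 volumes; tests and the acceptance script use 64×64×8 volumes
with proportionally scaled radii as their problem size. Volumes are
written as uncompressed NIfTI-1 with a fixed header policy, so identical
specs regenerate byte-identical files.

What the phantom does **not** emulate: real anatomy and texture,
multi-focal irregular lesion geometry, partial-volume effects, anisotropic
voxel spacing, registration error and scanner artefacts. Passing the
mechanism tests therefore demonstrates that the architecture, losses,
optimizer and pipeline are wired correctly and can fit structured
multimodal signal — not that the model reaches any particular accuracy on
clinical data.

## Training

Full-batch AdamW (β = 0.9/0.999, weight decay 0.01) on in-memory slice
stacks, learning rate 3e−3 by default: with full-batch gradients on a
small model, 1e−3 converges too slowly to pin down thin-structure
boundaries within a few hundred steps, while 3e−3 reaches near-perfect
overlap in the same budget. The mechanism check trains the tiny
configuration on 4 phantom slices for 300 steps and then requires argmax
self-prediction to reproduce the training labels per region (DSC and the
95th-percentile Hausdorff distance). Loss components are logged per step;
checkpoints store the weight arrays plus a JSON sidecar with the full
model configuration, package version and step counter, and loading
verifies config/weight consistency.

## Known limitations

* 2-D slice model only; no volumetric operators, deep supervision or
  test-time augmentation.
* The scan is a sequential Python loop (vectorised over batch, channels
  and directions); it is fast enough for desk-scale work but not for
  dataset-scale training.
* The boundary-loss surrogate is one-sided (penalises outward mass only);
  inward errors are handled by the overlap terms.
* The reported-scale benchmark numbers of full-scale systems (training on
  the real BraTS datasets) are out of scope; nothing here reproduces them.
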