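# Methods

## Problem and model

The task is binary semantic segmentation of insect pests in field crop
imagery: every pixel is classified as pest (1) or background (0). The
difficulty profile is characteristic of field data — pests are small
against a dominant background, appear at multiple scales within a frame,
carry appendages one or two pixels wide, and sit on textured, slowly
varying vegetation with modest contrast. The architecture is a symmetric
U-shaped encoder–decoder whose token mixer is a 2D selective-scan
state-space model (SS2D) rather than convolution or attention, giving a
global receptive field at cost linear in the pixel count.

### Selective scan (S6 / SS2D)

Each feature map is flattened along four traversals — row-forward,
row-reverse, column-forward, column-reverse — and each sequence is run
through the selective state-space recurrence

    h_t = Ā_t h_{t−1} + Δ_t B_t x_t,   y_t = C_t·h_t + D ⊙ x_t,
    Ā_t = exp(Δ_t A),   A = −exp(A_log)

with per-token `B_t, C_t ∈ R^N` and `Δ_t ∈ R^D` produced by learned linear
maps of the token (Δ through a softplus). Storing `A` as `−exp(A_log)`
keeps every transition in (0, 1]: the recurrence is unconditionally stable
and the hidden state is bounded by `max|Δ B x| / (1 − max Ā)` whenever
`max Ā < 1`. The four scanned outputs are inverse-permuted to spatial
layout and summed. Per-direction parameters are independent by default
(`tie_directions` shares them, which makes the layer equivariant to 180°
rotation — a property the tests exploit).

Numerical choices: zero-order-hold discretization for the transition with
the standard Euler simplification `B̄ = Δ·B`; `A_log` initialised to
`log(1..N)`; `Δ` bias drawn so initial steps lie in [1e-3, 0.1]
(log-uniform); skip `D` initialised to one. The recurrence is evaluated
sequentially in chunks (default 512 steps) purely for cache locality — the
contract, enforced by tests, is that chunk size never changes any value.
All four directions run as a single batched recurrence.

### Blocks

* **VSS block**: LayerNorm → linear expansion (ratio 2) →
  depthwise-separable 3×3 convolution + SiLU → SS2D →
  squeeze-excitation channel gate (reduction 4) → LayerNorm → linear
  projection → residual.
* **Multiscale VSS** (encoder): the VSS output is linearly projected, then
  refined by parallel 1×1/3×3/5×5 convolutions (dilation 1) summed and
  fused by a 1×1 convolution, with a second residual around the
  refinement.
* **Multiscale attention aggregation** (bottleneck): 1×1 projection →
  parallel 3×3 convolutions with dilation rates 1/3/5, summed → a
  single-channel spatial sigmoid gate computed by a 7×7 convolution over
  the 2-channel stack of channelwise average and max maps → the gated map
  plus the projected input through a final 1×1 convolution. The
  average/max-pool-and-convolve gate is the CBAM-style spatial attention
  construction; the trailing 1×1 convolution is channel-preserving and has
  no nonlinearity.
* **Channel-aware attentive skip**: `v = VSS(x)`, `f = Conv3×3(LN(v))`,
  output `gate(f) ⊗ f + v` with the same pooled-map sigmoid gate (3×3
  kernel at skip resolution). One residual (`+v`) is used.

The kernel-size/dilation split is deliberate: the encoder's multiscale
refinement varies *kernel size* (1/3/5 at dilation 1) while the bottleneck
varies *dilation rate* (1/3/5 at kernel 3), so the two modules probe scale
in complementary ways and remain distinguishable in ablations.

### Identity at initialisation

Every residual block's final projection is zero-initialised (and the
multiscale-VSS inner projection identity-initialised), so each block — and
therefore an arbitrarily deep stack — is the exact identity map at
initialisation. This is what makes a from-scratch SGD run stable at
desk scale; switching `zero_init_residual` off restores generic random
projections (used by the gradient-flow tests, which assert that every
parameter of every block receives a nonzero gradient).

Other weights use a truncated normal with flat std 0.02 (the convention of
Mamba/transformer-style vision models). A fan-in-scaled (LeCun)
alternative was evaluated and discarded: the larger initial weights
lengthen the all-background plateau of short SGD runs, whereas the narrow
flat scale keeps logits near zero so the softmax starts uniform and the
Dice term can lift the pest class immediately.

### Network assembly

Patch embedding (4×4, width C, default 96) → four encoder stages (2
multiscale VSS blocks each by default) with patch merging between → the
attention-aggregation bottleneck on the `H/32 × 8C` feature → decoder input
= bottleneck output + attentive skip of stage 4 → four decoder stages (2
VSS blocks each) with patch expanding, each fusing the attentive skip of
the matching encoder stage by elementwise addition (addition, not
concatenation, preserves the published channel ladder) → final 4×
expansion and a 1×1-convolution head to per-pixel logits. Softmax is
applied only at prediction time; the loss consumes logits. `use_msvss`,
`use_msaa`, `use_cavss` switch the three modules off individually,
reproducing the structural ablation axes.

## Loss and metrics

Hybrid loss `λ·L_CE + (1−λ)·L_Dice`, λ = 0.4, where CE is the mean
per-pixel negative log softmax probability of the true class and Dice is
the soft overlap `1 − 2Σŷy / (Σŷ + Σy + ε)` with ε = 0.001, summed over
classes and pixels jointly. Dice consumes softmax probabilities (not
argmax masks), which keeps it differentiable; both losses also accept
probability-valued targets so mixup's soft labels train unmodified.

Evaluation accumulates an n×n confusion matrix over all pixels of a split,
then reports PA (trace over total) and MIoU (mean over classes of
TP/union). Classes with zero union are excluded from the mean rather than
scored 0/0; with two classes and non-empty scenes this is a corner case
only. Accumulation makes both metrics exactly invariant to batch
partitioning.

## Training protocol

SGD with momentum 0.9, weight decay 1e-4, constant learning rate 1e-3,
batch size 24 (capped at the training-set size), 3,000 iterations by
default; validation PA and MIoU are computed from a fresh confusion matrix
every 200 iterations, and weights are persisted only on strict MIoU
improvement (PA breaks ties). No learning-rate schedule is used and
optimizer state is not checkpointed — only best weights. A non-finite loss
aborts with the offending iteration number. Batch sampling is driven
entirely by the configured seed.

## Synthetic scenes

The generator renders what makes the real task hard rather than what makes
it photogenic: elliptical bodies (scale 0.08–0.20 of the image diagonal,
eccentricity 0.40–0.75) with 3–6 thin polyline appendages (1–2 px) rooted
inside the body, darkened relative to the local background by a contrast
factor (default 0.5), on a green-tinted background with a random linear
gradient and two scales of filtered noise. Three pests per 64×64 scene by
default gives roughly 5–8 % foreground — realistic for field imagery and
deliberately imbalanced, since that imbalance is the stated reason for the
Dice term. Pseudo-categories vary pest count, scale and contrast
deterministically; an imbalance profile plus a rebalancing floor emulates
rare-class top-up with augmented copies, which the splitter then confines
to the training split.

What the generator does **not** emulate: real insect morphology and pose,
occlusion by foliage, specular lighting, camera blur, and inter-species
appearance similarity. Passing tests therefore demonstrate that the
architecture, losses, metrics and protocol are implemented correctly and
that the model can learn this class of small-object segmentation — not
that field-accuracy numbers transfer to real imagery.

## Augmentation

Geometric ops (crop ≥ 80 % area with resize-back, horizontal/vertical
flip, rotation ±30°, shift ≤ 10 % with reflection padding) transform image
and mask with identical parameters, the mask always nearest-neighbour so
codes stay in {0, 1}; right-angle rotations of square inputs take an exact
permutation path. Photometric enhancement jitters brightness/contrast
within ±20 % and touches the image only. Mixup produces soft probability
masks; CutMix transplants a rectangle of the requested area jointly in
image and mask and resamples degenerate boxes. Dataset-building is the
default place augmentation happens; training-time mixing is available as a
per-batch hook (`make_batch_mixer`, applying mixup with a Beta(0.4, 0.4)
coefficient or cutmix with a 10–40 % area fraction at configurable
probabilities) passed to the trainer, and is off by default.

## Scaled problem sizes

The published configuration (C=96, depth 2, 3,000 iterations) is exercised
for shape and protocol contracts; learning runs use a scaled-down model —
C=16, one block per stage, state size 4, eight 64×64 scenes, 300
iterations — chosen as the smallest configuration on which the
architecture demonstrably overfits the synthetic task (training PA > 0.95
from an all-background baseline of ~0.93). The optimizer settings for the
scaled runs are exactly the published ones.

## Implementation notes

The package carries its own reverse-mode autodiff on float64 numpy arrays
(`pestseg.tensor`): a small tape with explicit custom primitives for
stride-1 dense/depthwise convolution (k² shifted matmuls, symmetric zero
padding, odd kernels only) and for the selective scan, whose backward runs
the adjoint recurrence in reverse time with the same chunking contract.
Every primitive and layer is gradient-checked against central finite
differences in the test suite. Double precision is used throughout; the
scan oracle tests pass at 1e-9 relative tolerance.

## Known limitations

* Sequential (non-parallel-scan) recurrence: fine at desk scale, not
  suited to large images or real-time use.
* Binary head is the tested path; multi-class configuration exists but is
  untested beyond shape checks.
* The MIoU selection metric for checkpointing, the CBAM-style gate
  combiner, the additive skip fusion and the single CAVSS residual are
  design choices where the architecture description admits alternatives;
  each is localised behind a config field or a small module and documented
  above.
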