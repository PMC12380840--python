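# pestseg

Semantic segmentation of crop pests in field imagery with a **multiscale
vision-Mamba U-Net**: a symmetric encoder–decoder built from 2D
selective-scan state-space (SS2D) blocks, multiscale convolutional
refinement, a dilated-attention bottleneck, and channel-aware attentive
skip connections, trained with a hybrid Dice + cross-entropy loss.

## Who this is for

Researchers in agricultural image analysis who need per-pixel detection of
small insect pests — thin legs and antennae, several scales in one frame,
low contrast against textured vegetation — where plain U-Nets lose detail
to pooling and transformers pay quadratic cost for global context.
State-space (Mamba-style) visual models provide global receptive fields at
linear cost; this package implements a multiscale aggregated variant as a
tested, self-contained library plus CLI, including a synthetic field-scene
generator so the whole pipeline runs and is tested without any external
dataset or GPU.

## The model

An RGB image `Img ∈ R^{H×W×3}` (H, W divisible by 32) is split into
non-overlapping 4×4 patches and linearly embedded to width `C` (default
96). Four encoder stages at resolutions `H/4·C`, `H/8·2C`, `H/16·4C`,
`H/32·8C` are connected by patch merging (2×2 concatenation → LayerNorm →
linear to 2× channels). Each encoder stage stacks **multiscale VSS blocks**

    F_vss = VSS(LN(F)) + F
    F_out = MSDC(LP(F_vss)) + LP(F_vss)

where VSS = LayerNorm → linear expansion → depthwise-separable convolution
+ SiLU → **SS2D** → squeeze-excitation gate → LayerNorm → linear
projection, and MSDC runs parallel 1×1 / 3×3 / 5×5 convolutions fused by a
1×1 convolution.

**SS2D** flattens the map along four traversals (row-forward, row-reverse,
column-forward, column-reverse) and runs the selective S6 recurrence over
each sequence with input-dependent parameters `B_t, C_t, Δ_t`:

    h_t = exp(Δ_t A) h_{t−1} + Δ_t B_t x_t,     y_t = C_t·h_t + D x_t

with `A = −exp(A_log)` guaranteeing decay; the four scanned maps are summed
back in spatial layout.

The bottleneck applies **multiscale attention aggregation**: parallel 3×3
dilated convolutions (rates 1, 3, 5) under a spatial sigmoid gate built
from a 7×7 convolution of the channelwise average and max maps. Each skip
connection is a **channel-aware VSS**: `gate ⊗ Conv(LN(VSS(F))) + VSS(F)`.
The decoder mirrors the encoder with plain VSS blocks and patch expanding,
and a final 4× expansion feeds a 1×1-convolution softmax head over the two
classes, pest (1) and background (0).

Training minimises `λ·L_CE + (1−λ)·L_Dice` with `λ = 0.4` and Dice
smoothing `ε = 0.001`, by SGD (lr 0.001, momentum 0.9, weight decay 1e-4,
batch 24, 3,000 iterations), evaluating pixel accuracy `PA = ΣN_ii / ΣΣN_ij`
and mean IoU `MIoU = (1/n) Σ N_ii / (ΣN_ij + ΣN_ji − N_ii)` on the
validation split every 200 iterations and checkpointing only on a new best
MIoU.

Everything — including reverse-mode automatic differentiation, the
convolution and selective-scan primitives and their adjoints — is
implemented on numpy inside the package (`pestseg.tensor`, `pestseg.nn`).

## Worked example

```python
import numpy as np
from pestseg import (PestSegmenter, ModelConfig, TrainConfig, LossConfig,
                     generate_dataset, split_indices)

ds = generate_dataset(class_profile={"borer": 8, "roller": 4, "thrips": 2},
                      rebalance_floor=3, seed=1)
sp = split_indices(len(ds), ratios=(0.6, 0.2, 0.2), seed=1,
                   provenance=ds.manifest.provenance.to_numpy())

model = PestSegmenter(ModelConfig(base_channels=16,
                                  encoder_depths=(1, 1, 1, 1),
                                  decoder_depths=(1, 1, 1, 1),
                                  state_size=4, seed=1))
res = model.fit(ds.images[sp.train], ds.masks[sp.train],
                ds.images[sp.val], ds.masks[sp.val],
                train_config=TrainConfig(iterations=300, batch_size=8,
                                         eval_every=50, seed=1),
                loss_config=LossConfig())
res.restore_best()
print(res.summary())
pa, miou, _ = model.evaluate(ds.images[sp.test], ds.masks[sp.test])
print(f"test PA {pa:.4f}  test MIoU {miou:.4f}")
```

Output for this configuration and seed:

```
Pest segmentation fit
====================================================
base channels (C)                             16
encoder depths                      (1, 1, 1, 1)
parameters                             3,372,985
iterations                                   300
batch size                                     8
learning rate                              0.001
loss lambda (CE weight)                     0.40
final training loss                       0.0873
evaluations run                                6
best PA                                   0.9798
best MIoU                                 0.4919
====================================================
test PA 0.9578  test MIoU 0.5788
```

`best PA`/`best MIoU` are the validation metrics at the checkpointed
iteration; `final training loss` is the hybrid Dice+CE objective at the
last step. How to read these: a PA at the background fraction (~0.93 on
these scenes) with MIoU ≈ 0.47 means the model ignores pests entirely; PA
above it with MIoU above 0.5 means pest pixels are being recovered. Here
the short 300-iteration run has started segmenting pests on train and test
scenes (MIoU 0.58 on test), while on the 3-image validation split — which
drew the scenes with the smallest pest fractions (0.7–2.7 % foreground) —
MIoU still sits near the background-only value at the checkpointed step.
Longer runs (the published protocol is 3,000 iterations) drive all three
splits up.

The same pipeline is available from the shell:

```bash
pestseg synthesize --n 24 --out data/ --seed 1
pestseg train --data data/ --out runs/ --seed 1 --config config.yaml
pestseg evaluate --checkpoint runs/checkpoint.npz --data data/ --pred-dir preds/
```

where the optional `config.yaml` overrides any `ModelConfig`,
`TrainConfig` or `LossConfig` field:

```yaml
model:
  base_channels: 16
  encoder_depths: [1, 1, 1, 1]
  decoder_depths: [1, 1, 1, 1]
  state_size: 4
train:
  iterations: 300
  batch_size: 8
  eval_every: 50
loss:
  lam: 0.4
  epsilon: 0.001
```

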