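# Methods

## Problem and model

Automatic delineation of skin lesions in dermoscopy images is a binary
dense-prediction task: every pixel is lesion or background.  The difficulty
comes from irregular lesion geometry, low lesion/skin contrast, large scale
variation, and imaging artifacts — most prominently hair.  The package
implements MSDTCN-Net, a dual-encoder segmentation network that couples a
convolutional branch for local texture with a deformable-attention branch
for long-range context, and decodes through a hierarchy of additive skip
connections.

For a normalized input `X ∈ R^{3×224×224}`:

1. **Local branch.**  A ConvNeXt encoder (blocks
   `X + W2·GELU(W1·LN(DWConv7×7(X)))`) yields a four-level pyramid
   `C1..C4` with widths (96, 192, 384, 768) at strides 4–32.
2. **Context branch.**  A ResNet-34 produces five taps `R1..R5`
   (64→512 channels, strides 2–32; the first tap is taken before
   max-pooling to keep boundary detail).  Per-level 1×1 convolutions align
   all taps to width 256 (`R'_i = Conv1×1(R_i)`); the maps are flattened
   into one token sequence with sinusoidal position codes plus a learned
   per-level embedding, refined by a 12-layer deformable-attention encoder,
   and folded back into maps `T0..T4` via per-level 3×3 projections to
   widths (48, 96, 192, 384, 768).  Deformable attention samples each
   query's value at `heads × levels × points` predicted fractional
   locations (bilinear, zero-padded) instead of attending to all tokens,
   keeping cost linear in the token count (16 709 at 224²).
3. **Fusion.**  Per level, `F_i = Conv1×1(z_i ⊙ (C_i ‖ T_i))`, where
   `z_i = σ(FC2(ReLU(FC1(GAP(·)))))` are squeeze-and-excitation gates over
   the concatenated channels (reduction 16).
4. **MSRF.**  The multi-scale receptive-field block runs three
   width-preserving branches — 1×1; 1×1→1×3→3×1→3×3 (dilation 3);
   1×1→1×5→5×1→5×5 (dilation 3) — concatenates them, fuses with a 3×3
   convolution and adds the input.  The medium/large convolution chains
   have 9×9 and 17×17 receptive fields.  MSRF is applied to `F1..F3` and to
   the shallow context map `T0`; the deepest fused map `F4` feeds the
   decoder directly.
5. **Decoder and head.**  `D4 = F4`; `D_k = Up(D_{k+1}) + F_k^{MSRF}` down
   to `D0 ∈ R^{48×112×112}`, with `Up` a channel-halving transposed
   convolution (kernel 4, stride 2, padding 1; a bilinear+1×1 alternative
   is selectable).  The head is ConvTranspose(48→32, k4 s2 p1) → two 3×3
   convolutions (32→32→n_classes), producing full-resolution logits;
   sigmoid is applied outside the model.
6. **Objective.**  `L = 0.6·L_BCE + 0.4·L_Dice` on probabilities, with the
   soft Dice `1 − (2Σpy + ε)/(Σp + Σy + ε)`, `ε = 1e-6`, and probabilities
   clamped at 1e-7 before logarithms.

Evaluation uses pixel confusion counts at threshold 0.5 and reports
ACC, IoU, Dice, sensitivity and specificity; dataset scores average
per-image metrics (a global-pixel pooling switch is not provided — per-image
averaging is the package's convention).  For one confusion table
`Dice = 2·IoU/(1+IoU)` exactly.

## Key parameter choices

| parameter | default | rationale |
|---|---|---|
| ConvNeXt stage widths | (96, 192, 384, 768) | fixed by the C-pyramid ledger |
| ConvNeXt stage depths | (3, 3, 27, 3) | reaches the reference capacity of the full architecture (≈108 M trainable parameters); the lighter (3, 3, 9, 3) variant (≈86 M) is available via `ModelConfig` |
| transformer depth / width | 12 / 256 | fixed by the branch design |
| heads, points, FFN width, dropout | 8, 4, 1024, 0.1 | conventions of the deformable-attention encoder this branch follows; offset heads start at zero weights with direction-spread biases, weight heads start uniform |
| SE reduction | 16 | standard bottleneck ratio |
| optimizer | Adam, lr 1e-3, betas (0.5, 0.999), weight decay 0, batch 4 | training configuration of the reference setup; the low first-moment beta makes updates track current gradients |
| checkpointing | best validation Dice (per-image average, threshold 0.5) | model-selection rule |
| hair removal | 17×17 rectangular black-hat, threshold 10/255, biharmonic inpaint | the kernel must exceed a stroke width (1–5 px); threshold and kernel are configurable because thin-structure statistics vary between imaging setups |

Up-steps are bare transposed convolutions (no normalization/activation),
matching the style of the printed head; the head's two hidden stages are
followed by ReLU.  MSRF's internal convolutions carry BatchNorm+ReLU; the
fusion convolution's output is added to the input without a final
activation, so zeroing all weights reduces the block to the identity.

## Synthetic data

The generator emulates the gross statistics of dermoscopy datasets rather
than their appearance in detail: a low-frequency skin-tone background; one
connected, star-convex lesion per image whose radial boundary
`r(θ) = r_ellipse(θ)·(1 + 0.25·n(θ))` is perturbed by smooth Fourier noise
(orders 2–6); lesion area fraction drawn from [0.05, 0.40] and enforced by
rejection sampling on the rasterized mask; darker/browner lesion interior
with its own texture and a ~1.5 px feathered edge; and dark antialiased
quadratic-Bézier hair strokes (width 1–3 px, 6 per image by default) drawn
over the image only.  (cfg, seed) determines every output byte, so paired
renderings that differ only in `hair_count` share background, lesion and
mask exactly — this is what the hair-removal efficacy checks rely on.

What passing tests on this generator do **not** show: robustness to real
dermoscopic appearance (color constancy, gel bubbles, rulers, multi-lesion
scenes, ambiguous boundaries) or benchmark-level accuracy on ISIC/PH2;
those require the real collections and full-scale training.

## Numerical and implementation choices

The network, and the reverse-mode autograd tensor library underneath it,
are implemented on numpy: dense convolutions gather per-sample im2col
buffers and run single-threaded BLAS sgemm (the gather/scatter loops and
the multi-scale bilinear sampling kernels are numba-compiled); backward
passes re-derive padded inputs and normalization statistics from still-live
parent activations instead of caching them, and the tape releases interior
activations as it unwinds, so peak training memory stays near one copy of
the activations plus optimizer state.  GELU uses the tanh approximation.
All arithmetic is float32.

Weight initialization: truncated-normal (0.02) for ConvNeXt, He for
ResNet/decoder convolutions, Xavier for attention/FFN projections, zeros
for biases.  Note that the deformable offset and weight heads are
zero-initialized by design, so the positional level embedding receives its
first nonzero gradient only after the first optimizer update.

Degenerate inputs: metrics with empty denominators return 1 when the
prediction agrees the class is absent, else 0; sampling locations outside
[0, 1]² contribute zero (zero-padded bilinear interpolation); MSRF accepts
any spatial size ≥ 1 through same-padding.

## Scaled-down check sizes

CPU-scale checks use reduced problem sizes chosen as the package's own
operating points: structural tests run at 64² inputs with single-block
ConvNeXt stages and encoder depths 0–2; the overfitting smoke check trains
on four 224² synthetic samples with the attention encoder at depth 0 (depth
reduction is the smoke-variant knob; the degenerate 0-layer encoder leaves
alignment, embeddings and output projections in place) under the default
optimizer settings, capped at 200 steps and stopped once training Dice
exceeds 0.90 — under these conditions it converges within the first handful
of steps.  Optimization through the attention path itself is verified
separately by the gradient-flow check (every parameter receives a nonzero
gradient after one warm-up update).  The default
full-depth model is still constructed and run forward end-to-end to verify
capacity and the shape ledger.

## Known limitations

* No pretrained backbone weights are bundled; training from random
  initialization at desk scale demonstrates optimization behaviour, not
  benchmark accuracy.
* Single-device, float32, CPU-oriented execution; no distributed training,
  no mixed precision, no test-time augmentation, no deep supervision.
* Hair repair uses biharmonic inpainting; very dense hair that merges into
  large connected mask regions both slows the solve and degrades fill
  quality.
* The hair threshold (10/255) is tuned to thin dark strokes on brighter
  skin; faint blond hair on dark skin will be under-detected.
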