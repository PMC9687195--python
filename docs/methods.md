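# Methods

## Problem and model

`phf3` implements a dual-branch hybrid classifier for 4-level severity
grading of endoscopic images on the Mayo endoscopic subscore (MES 0–3).
The two branches see the same image and exchange information stage-wise:

* **Transformer branch** — a four-stage pyramid vision Transformer.
  Each stage tokenizes its input map with an *overlapping patch embedding*
  (strided convolution, kernel > stride, then token layer normalization),
  runs a stack of pre-norm residual blocks, and closes with one layer
  normalization before reshaping tokens back to a spatial map. A block is
  `x + MHA(LN(x)); x + CFF(LN(x))`. Attention queries keep full resolution;
  keys and values first pass through *spatial reduction*
  `SR(x) = LN(flatten(Conv(reshape(x), k=s=Rs))·W_S)`, cutting attention
  cost by `Rs²`. The feed-forward block expands `d → d·Rm`, applies a
  depthwise 3×3 convolution on the token map (local continuity), GELU, and
  projects back. The full-size plan is `d = [64,128,320,512]`,
  heads `[1,2,5,8]`, `Rs = [8,4,2,1]`, `Rm = [8,8,4,4]`,
  depths `[3,8,27,3]`.
* **CNN branch** — a ResNet50-style stem (7×7/2 conv + BN + ReLU + 3×3/2
  max-pool) and four bottleneck stages with channels
  `[256,512,1024,2048]` and blocks `[3,4,6,3]`.

Both branches produce 56/28/14/7-pixel maps for a 224 input, which is what
makes stage-wise fusion possible. After stages 1–3 the **feature fusion
module** mixes the two maps at channel level,

    M_pvt, M_cnn = Split(G_fuse(Concat(F_pvt, F_cnn)))
    F'_b = F_b + G_b(M_b),   b ∈ {pvt, cnn}

with `G_fuse` a 1×1 convolution + ReLU over the concatenated channels and
`G_pvt`, `G_cnn` plain 1×1 convolutions; the fused maps are written back
into *both* branches as the next stage's input. After stage 4 the branch
maps are concatenated channel-wise (2560 channels at full size).

### Second-order pooling head

The main head replaces global average pooling with the square-root-
normalized covariance of the stage-4 features. With `X ∈ R^{C×S}`
(`S = H₄·W₄` spatial positions):

1. `Σ = X·Ī·Xᵀ`, `Ī = (1/S)(I − (1/S)·11ᵀ)` — per-image covariance;
2. `A = Σ / tr(Σ)` — trace pre-normalization, guaranteeing all eigenvalues
   of `A` lie in `[0,1]` so the iteration below converges;
3. `L` coupled Newton–Schulz steps, `Y₀ = A`, `Z₀ = I`,
   `Y_l = ½Y_{l−1}(3I − Z_{l−1}Y_{l−1})`,
   `Z_l = ½(3I − Z_{l−1}Y_{l−1})Z_{l−1}` — multiplication-only matrix
   square root, GPU/BLAS-friendly (no eigendecomposition);
4. `Ŷ = √tr(Σ)·Y_L` — post-compensation restoring the data scale;
5. the upper triangle of `Ŷ` (row-major, diagonal included;
   `C(C+1)/2` values) feeds the final fully connected layer.

Gradients flow through the unrolled iteration; no implicit
differentiation. `L = 8` by default. `L = 0` keeps the un-rooted
covariance; `sop_mode="gap"` swaps the head for global average pooling —
the two readings of a "no second-order pooling" ablation, both exposed.
Covariance is computed per image (the formula carries no batch index).

**Approximation quality of L = 8.** The L-step iterate is exact only in the
limit; its error grows with the matrix size and spectrum spread because
trace normalization shrinks every eigenvalue as C grows. Measured against
an eigendecomposition square root on trace-normalized SPD matrices with
geometric spectra at condition number 100, the relative Frobenius error at
L = 8 is ≈ 5e-4 (C = 4), 2e-3 (C = 8), 7e-3 (C = 16), 1.2e-2 (C = 24),
1.8e-2 (C = 32); at L = 30 it is at machine precision for all of these.
The residual bias at L = 8 is a property of the plain (unscaled) iteration,
not of this implementation, and is deliberate — more iterations do not help
generalization, which is why L = 8 is the default rather than a larger
value.

### Objective and metrics

Three heads are trained jointly: two auxiliary heads (global average
pooling + FC on each branch's stage-4 map) and the covariance head. Each
gets label-smoothed cross-entropy

    L = (1−ε)·mean_n[−log p_{y_n}] + ε·mean_{n,k}[−log p_k],  ε = 0.1,

and the total is `α·L_pvt + β·L_cnn + γ·L_combine` with `α:β:γ = 1:1:2`.
At inference only the covariance head is read (argmax; probabilities are
its softmax). Evaluation reports a K×K confusion matrix, one-vs-rest
ACC/SEN/SPE/PPV/NPV/F1 per class, total accuracy and one-vs-rest AUC.
Zero-denominator rates are reported as missing (NaN + flag), never coerced
to 0, to avoid silently inflating per-class tables.

## Numerical core

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine on NumPy (`phf3.autograd`) — a define-by-run
tape with explicit backward closures for convolution (im2col/col2im,
grouped/depthwise), max-pooling, layer/batch normalization, softmax and the
usual elementwise/matrix operations — plus a thin layer library and an SGD
optimizer (`phf3.nn`). Network computation is single precision; the
functional covariance-pooling API preserves float64 inputs so oracle
comparisons are not precision-limited. Softmax and log-softmax use
max-subtraction; the trace denominator carries a 1e-12 guard so constant
feature maps yield zero features rather than NaN. Every gradient path is
finite-difference tested.

## Preprocessing and augmentation

CLAHE is applied deterministically to every image (train and test) on the
lightness channel in CIELAB — it is contrast enhancement highlighting
vascular texture and ulcer heads, not a stochastic augmentation (a
stochastic variant is available by config). Clip limit and tile grid
follow scikit-image conventions (`clip_limit = 0.01`, 8×8 tiles). Then:
resize to 256, random 224 crop, horizontal/vertical flips with p = 0.3
each (train) or center crop (test), and per-channel normalization with
ImageNet statistics (the full-size branches are designed for
ImageNet-pretrained initialization; synthetic runs may switch to dataset
statistics). Desk-scale runs use the same pipeline at 72 → 64 pixels,
keeping the resize-to-crop ratio.

## Synthetic data

The clinical dataset behind the method is private, so the package ships a
seedable generator (`phf3.synth`) whose four classes mirror the MES visual
hierarchy: grade 0 — pale mucosa with a clear vascular pattern (thin
dark-red random-walk curves); grade 1 — diffuse erythema blotches with a
decreased, faint vascular pattern; grade 2 — marked erythema plus small
bright erosion spots; grade 3 — one large irregular dark-red
bleeding/ulceration region (pixel mask returned, used by the Grad-CAM
localization check). All classes share a lumen-like radially darkened
background with illumination tilt and Gaussian noise. Identical spec +
seed give byte-identical PNGs. Defaults (200 images/class, 64 px,
noise σ = 4) were fixed once so that a multinomial-logistic baseline on
per-channel means/stds reaches well above 70% held-out accuracy — classes
are learnable but not trivially linearly separable at pixel level. The
generator emulates coarse color/texture statistics only: no specular
highlights, motion blur, optics or anatomy. Passing tests on it show the
architecture and training loop can extract the intended feature hierarchy;
they say nothing about clinical performance.

## Training protocol and presets

SGD with momentum 0.9 and weight decay 1e-5; learning rate multiplied by
0.1 every 10 epochs. The `paper` preset keeps the published protocol
(lr 1e-3, batch 128, 50 epochs, no covariance channel reduction) and is
exercised for shape/contract correctness — training it needs
GPU-scale hardware and pretrained branches. The `tiny` preset (Transformer
dims [16,32,64,128], one block per stage, heads [1,2,4,8], Rs [4,2,2,1],
Rm 2; CNN plan [32,64,128,256], one bottleneck per stage; 64-px inputs;
batch 16; 30 epochs) trains from random initialization, so its default
learning rate is 0.05 — the 1e-3 of the full protocol assumes pretrained
branches and barely moves a random tiny model. The covariance head reduces
the 384 concatenated channels to 64 by a 1×1 convolution before pooling
(C = 384 covariance costs ~36× more); the full-size default keeps the
literal design (no reduction). Per-epoch randomness (shuffle, crops,
flips) is drawn from a generator re-seeded from `(seed, epoch)`, so a
resumed run is bit-identical to an uninterrupted one from any epoch
boundary, and same-seed runs have identical loss curves. Execution is
deterministic throughout (single-threaded NumPy/BLAS); the
`deterministic` config flag is reserved.

Problem sizes used by the shipped verification runs: the end-to-end checks
train the tiny preset on 200 synthetic images per class with 50 per class
held out, 30 epochs; numerical oracles use matrices up to C = 32 (and one
full-size 224-px forward pass for the shape contract).

## Design choices where the design was open

* Stage-1 patch embedding: kernel 7, **stride 4**, padding 3. A stride of 3
  would give 75×75 stage-1 maps that cannot meet the CNN branch's 56×56 for
  fusion; stride 4 restores the geometry (and is the established
  convention for this embedding). The stride is exposed in the stage
  config.
* Stage-end normalization is applied before maps are handed to the fusion
  module.
* No explicit positional embedding: the zero-padded overlapping embedding
  and the depthwise convolution carry positional information.
* `G_fuse` is a single 1×1 convolution + ReLU; `G_pvt`/`G_cnn` single 1×1
  convolutions without activation or batch normalization, applied before
  the residual add.
* Auxiliary heads are always trained, never ensembled at inference; the
  covariance head is the model's output.
* Grad-CAM targets the CNN branch's stage-4 map by default (crispest
  spatial gradients); the Transformer stage-4 map and the concatenation
  are selectable.
* Labels are 0-based internally.
* Batch size is treated as free (the loss is normalized by N); the
  published 128 is kept in the `paper` preset.

## Known limitations

* CPU-only, single-device; the full-size preset is validated for shapes
  and finiteness, not trained here.
* The synthetic generator is a statistical stand-in, not an endoscopy
  simulator; reported accuracies on it do not transfer to clinical data.
* The Newton–Schulz head at L = 8 carries the spectrum-dependent bias
  quantified above; exactness is available via large L at extra cost.
* Checkpoints store raw arrays keyed by dotted parameter names; importing
  externally pretrained branch weights requires mapping names onto this
  schema (`Module.load_state_dict`).
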