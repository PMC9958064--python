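# Methods

## The model family

The package builds compact image classifiers for small labeled collections
(hundreds to a few thousand images, ≤10 classes), where full pretrained
networks are wastefully large. The construction has four stages:

**Compressed backbone (CEN).** Only the entry of EfficientNetB0 is kept: the
3×3/2 stem convolution (32 channels, BN, swish) followed by entry
inverted-bottleneck (MBConv) blocks at 16 channels. Each MBConv here is the
expansion-free entry variant: k×k conv → BN → swish → 3×3/1 depthwise conv →
BN → swish → squeeze-and-excitation gate (GAP → pointwise conv/swish →
pointwise conv/sigmoid → channelwise multiply) → swish. The first block
("A") strides by 2; subsequent blocks ("B") are its stride-1 twins. Blocks
are appended greedily, whole blocks at a time, while the running trainable
parameter total stays ≤ 20,000 — the hard compression budget. With the
EfficientNet convention that convolutions followed by BN carry no bias, the
greedy cut lands at stem + A + 5×B = 19,192 parameters. The exact layer
inventory inside the budget is this package's own design choice; the budget
and block vocabulary are the fixed points.

**Feature fusion (FCEN).** Truncation costs feature diversity. Two CEN
branches with identical architecture but independent random initializations
process the same input, and their feature maps are fused by elementwise
addition, `x_fused = F¹(H×H) ⊕ F²(H×H)`. Fusion doubles the feature
generators without deepening the network.

**Modified residual skip block (MRSB).** The fused features pass through one
residual unit, `R = ℱ(r) + r` with `ℱ = PWConv(SeLU(DWConv₁ₓ₁(r)))`: a 1×1
depthwise convolution (depth 1), SeLU, a 1×1 pointwise convolution, and an
identity skip with no activation after the addition (pre-activation style).
No k>1 convolution appears in the block, which keeps it far cheaper than a
stacked-conv residual unit. SeLU — λ·x for x>0, λ·β·(eˣ−1) for x≤0 with the
canonical self-normalizing constants λ≈1.0507, β≈1.6732 — supplies the
regularizing, variance-preserving nonlinearity; exactly one MRSB sits
between fusion and the head.

**Head.** GAP → dense(num_classes) → softmax. The dense layer's pre-softmax
outputs stay addressable as logits for distillation.

## Knowledge distillation

Training is two-stage. A teacher (any model exposing logits; the bundled
reference teacher is a small two-stage CNN suited to CPU-scale experiments)
is first trained conventionally: categorical cross-entropy, Adam, learning
rate 1e-4, batch 16, 30 epochs. The student then trains against the frozen
teacher with the tempered-softmax objective:

    Q(τ)  = softmax(L/τ)                     (soft distributions)
    Soft  = KL( Q_teacher(τ) ‖ Q_student(τ) )
    Hard  = CCE( Q_student(1), labels )
    Total = Soft·(1−α) + Hard·α

with τ = 2, α = 0.3, Adam at learning rate 1e-3 and otherwise the same
schedule (the distillation stage reuses the 30-epoch/batch-16 protocol with
only the learning rate changed). Design points worth stating explicitly:

- The temperature divides both teacher and student logits, so τ=1 collapses
  the soft term to the plain KL between the two softmax outputs.
- The KL direction is KL(teacher ‖ student).
- No τ² factor rescales the soft loss; the objective is implemented exactly
  as written above.
- Gradients flow only through the student; teacher weights and its
  batch-norm statistics are frozen.

## Cost model

All accounting is exact integer arithmetic on the layer graph. A standard
convolution (kernel H_K, channels C→C′, output feature size H_F) costs
H_K²·C·C′·H_F² multiplies; its depthwise-separable factorization costs
H_K²·C·H_F² + C·C′·H_F², a ratio of exactly 1/C′ + 1/H_K² — hence the ≈×9
saving for 3×3 kernels at wide outputs. Forward FLOPs are charged as
H²·(C·K+1)·C′ per convolutional layer, where K is the kernel *area* (the
area reading is required for the formula to count 2-D kernels and the +1
bias/accumulation term consistently) and H the *output* spatial size, and
(2I−1)·O per dense layer. BN, activations, pooling, additions and gates are
charged zero FLOPs: the accounting covers the compute-dominant layers only,
and every reported total states that convention. Under these conventions
the full student at 224×224×3 profiles to ≈0.131 GFLOPs and 38,790
parameters, comfortably inside the 0.33 GFLOPs envelope the architecture is
designed against.

## The numpy runtime

Graphs instantiate into a small NHWC float32 runtime written on numpy:
im2col convolutions, per-channel depthwise kernels, batch normalization with
momentum-0.9 running statistics, Adam (β₁=0.9, β₂=0.999, ε=1e-8).
Initialization is LeCun-normal, the variance-preserving choice SeLU assumes;
each layer draws from a generator derived from (model seed, layer name), so
the two fused branches differ stochastically while whole models are
bit-reproducible per seed. Gradient correctness is enforced by
finite-difference tests over every parameterized layer kind. float64 is
available (`Model(..., dtype=np.float64)`) and is what the gradient tests
use; training defaults to float32 for speed.

## Synthetic study conditions

The generator emulates a small labeled photograph collection with six
procedurally distinct classes: an oriented sinusoidal grating (angle
180°·c/6, frequency 3 + c mod 3, random phase per image), a class-specific
layout of three Gaussian blobs (fixed per class given the dataset seed), a
subtle class tint, and additive Gaussian pixel noise, clipped to [0,1] and
quantized to 8-bit PNG. At noise 0 the classes are linearly separable from
raw pixels; separability degrades smoothly with noise.

Default conditions — 6 classes × 60 images at 32×32, noise σ = 0.075, 80/20
stratified split — were fixed once so that the plainly trained student
finishes validation in the high-80s/low-90s percent range, leaving visible
headroom for distillation. The paired-run experiment (teacher, plain
student, distilled student, five seeds) checks the *ordering* — the
distilled student matches or beats its plainly trained twin — not any
absolute accuracy. What passing does not show: robustness to the nuisances
of real photographs (pose, lighting, background clutter, class imbalance),
or the benefit of ImageNet pretraining, which the protocol supports as an
optional weight load but never exercises. The plain student is also more
underfit here than a fine-tuned one would be, since every run starts from
random weights; the calibration of σ absorbs that.

The 32-px problem size keeps the full five-seed experiment in the
single-digit minutes on one CPU core; the builders accept any size ≥ 32 and
all analytic results are reported at the 224-px EfficientNet-native
resolution.

## Numerical choices and degenerate inputs

- Tempered softmax is max-shift stabilized; probabilities are clamped at
  1e-12 inside both losses.
- 'same' padding with ceil(H/stride) output everywhere; odd kernels only in
  practice.
- Splitting rounds half-up on the training side (600 → 480/120, 591 →
  473/118); published manifests whose printed splits deviate from 80/20 are
  taken as authoritative rather than re-split.
- Per-class metrics are one-vs-rest over all evaluated samples; the overall
  row weights per-class Pr/Rc/F1 by validation counts (the overall F1 is the
  weighted mean of per-class F1s, not recomputed from overall Pr/Rc), and
  percentages round half-up to two decimals. A zero denominator reports the
  metric as undefined with a warning, never as 0.
- Confusion-matrix, cost and ratio arithmetic is integer/Fraction exact.

## Known limitations

- The runtime targets small graphs; it is single-threaded numpy and not a
  general autodiff system (depthwise depth multiplier Ψ>1 is represented in
  the graph language but not instantiable).
- FLOPs exclude BN/activation/pooling work by convention, so totals are not
  comparable with profilers that count every op.
- ImageNet weight loading is shape-matched only; no weight translation from
  other serializations is attempted.
- The synthetic task is far easier than photographic species identification;
  absolute accuracies here say nothing about field performance.
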