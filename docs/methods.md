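# Methods

## Model

The classifier has three pathways over a single input image (grayscale or
RGB, resized and scaled to [0, 1]).

**Backbone.** Stages of Fused-MBConv blocks (3×3 expansion convolution +
1×1 projection; a single 3×3 convolution when the expansion factor is 1)
followed by MBConv blocks (1×1 expansion, 3×3 depthwise, 1×1 projection),
SiLU activations, residual connections where stride 1 and matching channel
counts allow. The default is three stages (8, 16, 16 channels, stride 2
each), about 10k parameters with the rest of the model — deliberately small
so the full two-stage protocol runs in seconds on one CPU core. An optional
per-stage channel gate (global average pool → bottleneck MLP → sigmoid,
multiplied back onto the channels) realises the supporter insertion into the
convolutional stages; it is off by default and exposed as a config switch
because the precise placement of that insert is a genuinely open design
choice. No pretrained weights are used anywhere.

**Transformer encoder.** The backbone's final map is patched P×P in
row-major raster order (default P = 2 on a 4×4 map, N = 4 tokens, embedding
dimension 16, 2 heads, depth 2). Blocks are *post*-norm —
LayerNorm(z + MHSA(z)) then LayerNorm(z + FFN(z)) with a ReLU FFN — rather
than the pre-norm arrangement of modern ViTs; the post-norm order is the
contract this architecture specifies, and at depth ≤ 2 the usual pre-norm
stability argument carries no weight. There is no class token: the
transformer's own (auxiliary) head acts on the concatenation of all N patch
outputs, which is exact but grows linearly in N — acceptable at desk scale,
and the reason the fused head (below) uses pooled summaries instead.

**Supporter pathway.** The last S stage outputs (default S = 3) are each
channel-averaged to one plane, average-pooled to a common spatial size
(capped at 4×4 so the raster sequence stays short), and stacked into an
(N, S, H, W) volume whose depth axis is *provenance*, not physical depth. A
single same-padded 3-D kernel (default 3×3×3) mixes depth and space. The
result is rastered row-major into T = H·W steps of S-dimensional vectors,
encoded by a BiLSTM (hidden 8 per direction), and pooled by additive
attention into a context vector c ∈ R¹⁶. A 1×1 channel-mixing projection is
provided for returning a recalibrated map onto a residual stream. Raster
order is a convention; any fixed order gives an equivalent model family.

**Fusion head.** softmax over a linear map of
concat(GAP(F_CNN), mean of transformer tokens, c). Pooling before fusion
bounds the head size regardless of image size.

## RL reweighting

- **State** (agent observation): per-class mean predicted probability and
  per-class running recall over a sliding window of 256 samples, plus the
  current weight vector — 3C numbers. Raw feature maps are unbounded in
  size and are deliberately excluded from the state.
- **Actions**: 2C+1 — raise or lower one class weight by factor β = 1.2, or
  no-op. After each action the weight vector is projected back onto
  {w ∈ [0.25, 4.0]^C, mean(w) = 1}; the projection clips and rescales the
  unclipped coordinates so both constraints hold exactly, which keeps the
  overall loss scale stable while shifting emphasis between classes.
- **Reward**: +1 correct minority, −1 missed minority, +0.1 correct
  majority, 0 missed majority; a mini-batch emits the mean. The minority
  set defaults to classes with training frequency below 1/C.
- **Learner**: MLP Q-network (hidden 32, tanh), FIFO replay buffer
  (capacity 2048), uniform sampling (batch 32), squared Bellman-error loss,
  SGD step per environment step, target network synced every 100 steps,
  γ = 0.9. ε-greedy behaviour decays linearly from 1.0 to 0.05 over the
  first half of stage-2 steps; exploration itself already spends substantial
  time at elevated minority weights, which matters at desk scale where the
  Q-signal is short.
- One environment step = one training mini-batch; episodes terminate at
  epoch boundaries.

A value-iteration solver for tabular MDPs is included purely as the
independent oracle: on three small deterministic MDPs the DQN's greedy
policy must reproduce the exact optimal policy.

## Training protocol

Stage 1: Adam, lr 3e-3, 8 epochs (20 for the separable benchmark), batch 16,
uniform weights; best checkpoint by validation macro-F1. Stage 2: Adam,
lr 2e-3, 20 epochs, weights driven by the agent; best checkpoint again by
validation macro-F1. Lower rates (1e-3/1e-4) were insufficient for this
model size — at ~10k parameters and a few hundred images the loss surface
is noisy and the larger steps are needed to leave the majority-collapse
basin within the epoch budget; macro-F1 selection also protects the
reported model from the oscillation that weighted objectives induce late in
stage 2. Augmentation (rotation ≤ 20°, flips, zoom 0.9–1.1, shift ≤ 0.1;
magnitudes are package choices, as only the transform families are
standard) applies to training manifests only; the API takes separate
train/validation manifests so validation and test data cannot be augmented.

Splits are per-class 70/15/15 by largest remainder with ties resolved
train > val > test. This reproduces most published per-class split rows
(e.g. 813 → 569/122/122, 150 → 105/23/22) but not all — the published
tables follow no single consistent rounding rule, so one rule is fixed and
documented rather than claiming row-exact agreement. Stratified k-fold
(default k = 5) partitions train+val with per-fold class proportions within
one sample of the global ones.

## Synthetic data

Each image is one elliptical cytoplasm containing one interior elliptical
nucleus on a light background in a Pap-stain-like palette; class identity is
carried primarily by the nucleus-to-cytoplasm area fraction (the classic
enlarged-nucleus marker of dysplasia), with class-dependent texture noise
and stain depth. Generation is fully determined by (spec, seed, size);
per-image seeds derive from a stable hash of (dataset seed, class id,
index) so any subset regenerates identically. PNG is the canonical output
(lossless); the loader also accepts BMP and JPEG.

Presets mirror the class structure of the two public Pap-smear collections:
seven classes with counts {146, 150, 197, 182, 98, 74, 70} (three normal,
four abnormal; total 917) and five classes with row counts
{813, 787, 825, 813, 793} against a printed grand total of 4049 — the rows
sum to 4031; both numbers are kept and the published group percentages
(39.5% normal / 40.5% abnormal) arise only from the printed denominator.
The imbalance study preset is two classes at 10:1 (200/20) whose
nucleus-fraction ranges overlap ((0.10–0.30) vs (0.26–0.46), noise sd 8):
enough overlap that short training does not trivially saturate minority
recall, as with real early-dysplasia cells.

What the generator does *not* emulate: overlapping/clustered cells, debris,
staining artefacts, focus variation, or any realistic texture. Passing
tests therefore certify the *mechanics* of the method — that reweighting
driven by the minority-focused reward recovers minority recall the uniform
baseline misses — not clinical performance on real cytology.

## The imbalance study

`cytorl.experiments.imbalance_experiment` fixes the study conditions:
10:1 training imbalance, 64 px renders preprocessed to 32 px grayscale,
stage 1 then stage 2 as above, minority recall measured before and after on
a balanced probe set of 40+40 images generated with an independent seed.
The probe set exists for measurement resolution only — the 15% test split
of 20 minority images would quantise recall in steps of 1/3. The package's
acceptance check runs this experiment over five paired seeds and requires
the median stage-2 minus stage-1 minority recall to be strictly positive.

## Numerical choices

- All computation in float64 on a reverse-mode autodiff engine over NumPy;
  every primitive's gradient is finite-difference-checked in the suite.
- Softmax and log-softmax subtract the (detached) row maximum.
- Cross-entropy clamps the true-class probability at 1e-12.
- Greedy action ties break to the lowest index; value iteration stops at a
  Bellman residual of 1e-10.
- A class with zero predicted positives gets precision 0 and is flagged in
  the per-class table; macro averages are plain unweighted means over
  classes. Multi-class specificity is one-vs-rest, macro-averaged, and the
  G-mean is √(macro recall × macro specificity) — the macro extension of
  the binary definition, stated explicitly because no standard multi-class
  form exists.
- Statistical branch gates (normality at α = 0.05) can be overridden with
  an explicit `method=` argument; Wilcoxon uses the exact distribution for
  n ≤ 25 without ties.

## Limitations

- Desk-scale by design: default images are 32×32 after preprocessing and
  the model is ~10k parameters. A 244×244 profile is configurable but slow
  on the NumPy engine.
- The stage-2 gain is demonstrated for two classes; with C classes the
  action space grows as 2C+1 and credit assignment will need longer
  horizons than the default 200 steps.
- The DQN's Q-values are validated on tabular MDPs; during classifier
  training no oracle exists, and the agent's benefit is assessed only
  through the end metric (minority recall).
- Checkpoints store raw float64 arrays; they are reproducible but not
  portable to other architectures' layouts.
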