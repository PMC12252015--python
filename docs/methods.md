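# Methods

This note documents the models, procedures and design choices behind
`rfcottnet`, in the order data flows through the pipeline.

## Scope and numerical substrate

The network, reverse-mode autodiff, AdamW, and the fake-quantization nodes
are implemented on numpy inside `rfcottnet.nn`.  The tape
(`nn/autograd.py`) provides exactly the primitives the models need —
grouped 2-D convolution (kernel-window loop with channel einsums), batched
matrix products, batch/layer normalization with hand-derived adjoints,
softmax, fused softmax-cross-entropy, and a straight-through
quantize-dequantize node — each verified against central-difference
gradients in `tests/test_autograd.py`.  All parameters are float32; the
quantize-dequantize node computes in float64 internally so that a very wide
bitwidth degenerates to an exact identity.

## Dataset construction

The target corpus structure is an 11-class cotton leaf disease/pest
image collection (10 disease or pest categories plus healthy), strongly
class-imbalanced, with published per-class totals of 18,953 images of which
14,177 came from online sources and 4,776 from 6-fold augmentation
(originals included) of 796 field photographs.  The package records those
totals (`data/types.py`) and reproduces the accounting exactly.

**Split rule.** The train/test split is per class: a class of size n
contributes floor(0.8·n) training images, remainder to test, membership by
seeded shuffle.  This per-class floor rule reproduces the published split
table row for row (15,159 / 3,794 overall; e.g. the healthy class of 6,444
splits 5,155 / 1,289), which a global shuffle does not.  By default
augmented variants travel with their original across the split boundary —
stricter than any published protocol; it prevents near-duplicate leakage,
at the cost that the floor rule then applies to origin groups rather than
raw images.  `group_variants=False` restores the exact per-image rule.

**Augmentation.** Five operators: multiplicative brightness (±30%),
horizontal/vertical flip, random rectangular masking (1–20 masks, sides
2–20% of the image side), Gaussian pixel noise (σ = 10 on the 0–255 scale),
and rotation (uniform ±30°, bilinear).  Ranges are package defaults — the
source protocol names the operators but not their strengths — and all are
configurable.  Each variant applies an independently drawn non-empty subset
of the operators that are active in the policy; the first output is always
the untouched original, so `variants_per_original = 6` turns 796 originals
into 4,776 files.  Draws are returned alongside the images, which is how
the tests check a rotation-only draw against an independent affine
transform.

**Synthetic renderer.** Real images are never required: the renderer draws
an elliptical leaf with midrib and veins on a textured background, and
encodes class identity in lesion count, lesion hue, leaf and background
hues, and texture noise.  The default 11 signatures spread hues across the
color circle; the healthy class carries no lesions.  This emulates the
*class structure* of a leaf-disease corpus — balanced lighting, centered
leaves, hue-separable classes — not real disease morphology, occlusion,
or field backgrounds.  Passing tests therefore demonstrate that the
pipeline is correct and the architecture can learn, not that the printed
full-scale accuracy transfers to real imagery.  All randomness descends
from one integer seed through splittable seed sequences; images re-render
byte-identically for a fixed seed.

## Backbone

The stage table follows the width-1.0 MobileViTv2 design: 3×3 stride-2 stem
(32), one MV2 block to 64, two to 128 (first downsampling), then three
[MV2-down + MobileViT] stages at 256/384/512 channels with attention widths
128/192/256 and transformer depths 2/4/3; global average pool and a linear
classifier.  MV2 blocks use expansion 2, batch norm and SiLU; transformer
layers are pre-norm with a 2× feed-forward.  Eq-level choices:

- The attention score normalizer is softmax (the source text leaves the
  normalization of the context scores implicit; softmax follows the cited
  architecture).  The score projection carries no bias: softmax is
  invariant to a constant shift, so such a bias would be a structurally
  dead parameter.
- ReLU gates the value branch inside attention even though conv blocks use
  SiLU (taken literally from the formula).
- MobileViT token grouping: patch size 2; pixels at the same intra-patch
  offset form one token group, so an 8×8 map yields 4 groups of 16 tokens.
  Odd spatial sizes are right/bottom zero-padded before unfolding and
  cropped after folding.
- The block output is fused with the block input by residual addition.

Default input resolution is 256×256 (configurable).  The full-width model
with an 11-class head counts 4,394,475 backbone parameters.

## Multi-exit heads and training

Three heads (1×1 conv with bias to `head_width`, ReLU, global average pool,
linear) tap the three MobileViT stages.  `head_width = 400` is fixed by
stage-table arithmetic so the complete model (4,869,708 parameters) lands
on the published 4.9 M budget while its INT8 export stays inside the
published 4.8 MB storage budget; both budgets are treated as architecture
design constraints.

The training loss is the unweighted sum of the four per-stage
cross-entropies (weights configurable).  The source material defines the
per-stage loss but not the combination rule nor whether the final
classifier participates; including it with unit weight is this package's
choice — it trains the only stage that is guaranteed to answer.  Optimizer
is AdamW (β = 0.9/0.999, weight decay 0.01) with a cosine learning-rate
schedule down to 5% of the peak.  Full-scale defaults follow the published
recipe (batch 128, learning rate 5e-5); the desk-scale preset (width/8,
64×64 images, 30 images per class, batch 32, peak 5e-3, 30 epochs) is
chosen to converge on one CPU in about a minute and reaches ≈95–98%
held-out accuracy on the synthetic corpus.

## Dynamic early exit

Two gate readings exist in the source material — confidence strictly above
per-stage thresholds (0.6, 0.7, 0.8) and entropy strictly below a threshold
S — and they are not equivalent.  Both ship behind `ExitPolicy.mode`;
confidence mode is the default because its constants are printed, and
neither is silently preferred: entropy mode takes a scalar (applied to
every stage) or a per-stage vector.  Ties do not exit (strict
inequalities, literally).  The final stage always exits, entropies are in
nats, and confidence thresholds above 1 (or entropy threshold 0) provably
disable early exit, making the cascade bit-identical to the plain
final-head pass — an invariant under test.  The cascade is evaluated
batch-wise on the samples still in flight, so stages after the last exit
are never computed (`stage_eval_count` makes that assertable).

## Quantization

The QAT recipe is the de-facto INT8 standard: symmetric per-output-channel
weights (codes in [−127, 127]), asymmetric per-tensor activations (codes in
[−128, 127]) with EMA min/max observers (momentum 0.99),
round-half-to-even, straight-through gradients with clipping.  Weight
scales are recomputed from the live weights every forward pass and rounded
to half precision, so the serialized file (which stores scales as float16)
reproduces the fake-quant forward bit-exactly.  First and last layers are
quantized like all others; attention projection matrices are quantized
per output column.  At range freeze, biases and normalization parameters
(and batch-norm statistics) are cast to half precision — the deployment
convention for non-weight parameters — which is what lets the export
round-trip exactly while keeping the file at about one byte per parameter.

The export container is an npz archive with one packed int8 code buffer,
one packed float16 buffer (scales, biases, norms, statistics), float32
observer ranges, and a zlib-compressed JSON index of shapes and offsets;
loading rebuilds the model from the embedded architecture descriptor and
reproduces the frozen forward pass exactly, so INT8 exit decisions match
the fake-quant model's by construction (and are tested on 100 inputs).
Re-export of a loaded model is byte-identical.  Auxiliary heads remain
attached through quantization so all exit paths survive export.

## Evaluation and profiling

Metrics come from the C×C confusion matrix: per-class precision
tp/(tp+fp), recall tp/(tp+fn), F1 = 2PR/(P+R) (0/0 → 0), aggregated
accuracy trace/total.  Table-level averages are macro (unweighted class
means) — the reading consistent with distinct printed precision/recall
values — with micro averages also emitted; for single-label multiclass,
micro precision = micro recall = accuracy, an identity under test.  The
one-vs-rest per-class accuracy (tp+tn)/total is exposed in the per-class
breakdown.  Percentages print to one decimal.

The profiler counts multiply-accumulates (1 MAC = 1 FLOP here):
convolution k²·cin·cout·Hout·Wout/groups, linear din·dout, separable
attention 3kd + 3kd² per token group; normalization and activations are
excluded — the convention under which the cited backbone's published
≈1.9 G figure at 256² is recovered.  Parameter counts are reported with
and without normalization layers, since published counts are ambiguous on
that point.  Per-exit cumulative cost uses cascade accounting: exiting at
stage i charges the trunk through stage i plus heads 1..i, which makes the
cumulative sequence monotone and the expected inference cost
Σ fraction_i · cumulative_i never exceed the full path.  Published FLOP
totals attributed to quantization are not reproduced: quantization does
not change operation counts, and no accounting convention recovering those
totals is derivable, so the profiler reports full-path and expected-cost
numbers separately.

## Problem sizes used by the tests

The suite trains the desk-scale preset once per session (30 images per
class, 64×64, 30 epochs — about 70 s on one CPU), fine-tunes its
fake-quant copy for 2 epochs, and reuses both across the exit, QAT and
parity tests.  The augmentation-accounting test renders the full 796
field images at 64×64 and materializes all 4,776 variants.  Full-width
(4.9 M parameter) checks construct and export the model but never train
it.

## Known limitations

- The synthetic corpus is far easier than field imagery; accuracy numbers
  on it say nothing quantitative about real-world performance.
- Convolution via kernel-window einsums is adequate for desk-scale work
  but one to two orders slower than a tuned BLAS/conv stack; full-scale
  training is supported in principle, not in practice.
- Wall-clock latency is hardware-dependent and out of scope; compute is
  compared in MACs only.
- Exit thresholds are fixed constants; learned or per-class gates are not
  implemented.
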