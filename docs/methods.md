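# Methods

## Problem and model

The package addresses converter vs. non-converter classification of
mild cognitive impairment (MCI) from 3D amyloid-PET volumes: an image
is a *converter* if its subject progresses to Alzheimer's disease
within 36 months of acquisition, a *non-converter* otherwise, and
*unlabeled* when follow-up is insufficient to decide. Labeled images
are scarce and imbalanced (roughly 1:3 converter:non-converter), while
a comparable pool of unlabeled scans exists — the setting
semi-supervised representation learning is built for.

Pre-training follows momentum contrast. Two stochastic augmentations
of an image give an anchor `x_a` and a positive `x_+`; a query network
`f_theta` embeds the anchor, a key network `f_phi` (same architecture,
parameters updated only as an exponential moving average of `theta`,
never by gradient) embeds the positive; embeddings are L2-normalized.
A FIFO memory queue stores the last K key embeddings as negatives.
The instance-discrimination loss is the softmax cross-entropy of the
positive against the queue at temperature tau:

    L_inst(i) = -log [ exp(z_a.z_+ / tau)
                       / (exp(z_a.z_+ / tau) + sum_k exp(z_a.z_k / tau)) ]

The package's distinguishing ingredient is a *label-aware* term: each
queue entry carries the conversion label it was enqueued with, and for
a labeled anchor the entries with the same label (the set `M_i`;
"unlabeled" never matches) are pulled toward the anchor:

    L_label(i) = -(1/|M_i|) sum_{m in M_i} log [ exp(z_a.z_m / tau) / Z ]

with Z the same denominator as above. The combined per-batch objective
is `mean_i [ L_inst(i) + alpha * L_label(i) ]`, where the label term is
zero for unlabeled anchors and for anchors with empty `M_i`.

Two readings of the label term are implemented — the mean-of-logs form
above and a log-of-mean variant that averages the probabilities inside
the logarithm — because the published formula is ambiguous on this
point (its numerator does not involve the summation index, which we
treat as a typographical slip, consistent with the stated intent of
pulling same-label instances). Mean-of-logs is the default: each
same-label entry receives an independent gradient pull, which is
better behaved when `|M_i|` is large.

## Architecture

The encoder is a 3D ResNet-50: a 3x3x3 stem convolution with stride 1
and padding 1 (replacing the conventional 7x7x7), a stride-2 max
pooling, four bottleneck stages (1x1x1 / 3x3x3 / 1x1x1, expansion 4,
stage depths [3,4,6,3], stride 2 at stages 2-4), and global average
pooling. The projection head is a two-layer MLP (hidden width = the
2048-d encoder feature width, the MoCo-v2 convention) with output
dimension 128, L2-normalized. For fine-tuning the projection head is
replaced by a single affine layer with softmax; encoder weights carry
over unchanged and all layers remain trainable.

Normalization is per-channel batch normalization by default, with a
group-normalization switch for very small batches where batch
statistics are unstable. A reduced spec (`EncoderSpec.reduced()`:
base width 8, one block per stage, 16-d projection) is used for all
desk-scale experiments and tests; the full spec is exercised once per
test run on a 72^3 volume.

Because no GPU tensor framework is part of the dependency stack, the
network layer (`smoco.nn`) is a self-contained reverse-mode autodiff
engine on numpy: im2col 3D convolution, fused batch/group
normalization, 2x2x2 max pooling, linear maps, AdamW. Every primitive
gradient is validated against central finite differences in the test
suite, and the batched contrastive loss against an independent
scalar-loop oracle.

## Training protocol

Defaults mirror the study protocol: temperature tau = 0.2, queue
capacity K = 1024, EMA coefficient 0.95 applied per optimizer step,
alpha = 1, AdamW (beta1 = 0.9, weight decay 0.01 — the decay value is
unstated in the source protocol and configurable), learning rate 1e-4
decayed to zero by a half-cosine schedule over all steps, batch 16,
100 pre-training epochs and 10 fine-tuning epochs (the fine-tuning
schedule is also half-cosine over its own 10 epochs). The queue is
pre-filled with K random unit vectors labeled "unlabeled", so the
denominator is well-conditioned from step one while `M_i` stays empty
until real keys arrive. Keys are enqueued after the batch loss, so an
anchor's own positive is never among its negatives within a step.
Unlabeled anchors simply skip the label term; no pseudo-labels are
ever assigned.

Fine-tuning rebalances every mini-batch to 1:1 by drawing half the
batch from each class (minority with replacement), and the operating
cutoff is chosen on validation scores by maximizing Youden's J
(sensitivity + specificity - 1), ties broken toward the higher
threshold; a prevalence-matching quantile rule is available as an
alternative. The cutoff rule is our concrete reading of "adaptive
cutoff", which the source protocol references but does not formulate.

## Data handling

Volumes are NIfTI; a manifest CSV maps each image to subject,
acquisition index and label. Spatial standardization zero-pads each
volume to a cube (centered, odd voxel to the trailing side) and
resamples by nearest neighbor with voxel-center alignment
(`src = floor((i + 0.5) * in / out)`) — documented exactly so tests
can be bit-exact. Labeled images are split 80/10/10 into
train/validation/test, repeated with different seeds (30 by default);
all unlabeled images join every training pool. Splits are stratified
by class by default so validation and test always contain converters
(the unstratified variant and an optional subject-level grouping —
which prevents a subject's scans from spanning partitions — are
flags). The 36-month labeling rule is accepted as a manifest column,
not computed from visit tables.

## Augmentation

The view transform is not specified in the source protocol; the
implemented family is standard contrastive practice adapted to
atlas-registered brains: random cubic crop (linear scale uniform in
[0.7, 1] by default, center-biased triangular offset, nearest-neighbor
resize back), left-right flip only (registered brains are
near-symmetric; arbitrary rotations would fight the registration),
voxelwise affine intensity jitter (scale SD 0.1, shift SD 0.1), and
additive Gaussian noise (SD 0.05). All parameters are configurable;
an identity preset exists for debugging and exact-reduction tests.

## Synthetic phantom

The phantom emulates the cohort structure without any clinical data:
an ellipsoidal "brain" (baseline 1.0 inside, 0 outside) on a cubic
grid; a cortical shell — normalized ellipsoidal radius in
[0.55, 0.75] — whose mean intensity is elevated by the effect size
delta for converter-distribution images, standing in for cortical
amyloid deposition; a per-subject Normal(0, subject_sd) offset shared
by all of a subject's images; and i.i.d. Normal(0, sigma) voxel noise.
Unlabeled images are drawn from the same mixture with a configurable
converter prevalence; their generating class is recorded in a sidecar
visible to tests but never to training code. Intensities are
arbitrary units, not calibrated SUVR — the method needs only relative
contrast. Default cohort sizes follow the ~1:3 labeled imbalance and
a roughly equal-sized unlabeled pool of the motivating study at desk
scale (40 + 120 labeled, 110 unlabeled, 2 images per subject).

What the phantom does **not** model: scanner point-spread, partial
volume, attenuation, registration error, anatomical variability, or
per-image class transitions within a subject (a phantom subject's
scans share one generating class). Passing tests therefore show the
*pipeline* behaves as specified — they do not certify performance on
clinical PET.

## Benchmark problem sizes

All quantitative experiments use the reduced encoder on a 16^3 grid
with 60 + 60 labeled and 120 unlabeled images (balanced classes keep
the 12-image validation/test sets informative), effect size 1.5 and
noise SD 0.5 — chosen so single-CPU runs finish in minutes while the
k-NN probe sits well away from both chance and ceiling:

* representation quality: 30 pre-training epochs, probe at the end,
  5 seeds per configuration;
* classification: 5 pre-training + 10 fine-tuning epochs;
* null control: effect size 0, shortened schedule (3 + 5 epochs) —
  AUROC is schedule-independent under the null;
* strong effect: delta 3.0, sigma 0.1, 5 + 10 epochs.

## Numerical choices and edge conventions

* All softmax terms use max-shifted log-sum-exp; losses are finite for
  unit-norm inputs at any temperature >= 0.01.
* Instance loss with an empty queue is 0; label loss with empty `M_i`
  is 0; label loss for an unlabeled anchor is an error (callers route
  unlabeled anchors around it).
* The per-batch objective is a mean, not a sum, so the learning rate
  is invariant to batch size; alpha semantics are unchanged.
* k-NN distance ties break by reference index (stable sort); AUROC
  counts score ties one half; cutoff ties resolve toward the higher
  threshold; classification predicts converter when score >= cutoff.
* Networks run in float32; loss oracles compare in float64 at 1e-5.
* Checkpoints store both networks, queue, optimizer moments, RNG
  states and progress; a save/load round-trip continues bit-identically
  on a single device.

## Known limitations

* Single-device contract: no shuffled batch statistics across devices,
  no data parallelism, no mixed precision.
* The numpy engine is CPU-bound; full-scale (72^3, ResNet-50, K=1024,
  100 epochs) pre-training is out of its intended range — the package
  targets method correctness and desk-scale experimentation.
* The phantom's simplicity means directional findings (e.g. the
  label-aware gain) are demonstrations on synthetic structure, not
  clinical claims.
* Comparator semi-supervised baselines (pseudo-labeling, virtual
  adversarial training, stochastic weight averaging) and a
  random-forest readout on embeddings are deliberately out of scope;
  `supervised_baseline` is the only reference model.
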