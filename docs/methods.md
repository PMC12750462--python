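# Methods

`fedcpi` implements a federated learning framework for binary risk
stratification from lesion-centered grayscale image patches held at multiple
hospitals, together with the synthetic multi-center benchmark and the clinical
model-comparison statistics used to evaluate it.  This note records the model,
its assumptions, the parameters that matter, and the design choices that were
genuinely open.

## The model

Each client (center) holds private images and binary outcome labels.  Two
encoders produce per-image feature vectors:

* a **large frozen encoder** standing in for a vision foundation model.  The
  default is a seed-pinned, randomly initialized convolutional stack with
  global average pooling; it is never trained, and any callable with the same
  contract (batch of images → fixed-dimension vectors), e.g. a pretrained
  ViT, can be substituted without touching the rest of the framework;
* a **small trainable residual CNN** (ResNet-style topology with a width
  multiplier, default 0.25).

The LMSF head aligns and fuses the two feature streams:

1. Both streams are linearly projected to a shared width and passed through
   bidirectional single-head cross-attention **over the batch** (each sample
   attends to every sample of the other stream) with residual connections.
   A cosine alignment loss `1 − mean cos(a_large, a_small)` shrinks the gap
   between the two streams.
2. The aligned pair is decomposed into four subspace blocks: **common**
   (one shared head applied to both streams, averaged), **personal-large**
   and **personal-small** (stream-specific heads), and **interactive** (head
   on the concatenated pair).
3. A supervised InfoNCE loss against a FIFO **queue** of past common-space
   embeddings with labels (temperature τ = 0.1) sharpens intra-class
   consistency.  Anchors without a same-label queue entry are skipped; an
   empty-positive batch contributes zero loss (warm-up).
4. A **gating network** emits four softmax weights per sample; the fused
   representation is the convex combination of the per-block projections, and
   a logistic head turns it into a risk probability.

The server applies subspace-aware aggregation (FACM) each round:

| group | tensors | rule |
|---|---|---|
| COMMON | common head, fusion projections, classifier | uniform mean (optionally sample-weighted) |
| PERSONAL | personal heads, gating network | never uploaded |
| INTERACTIVE | cross-attention, interactive head | softmax(validation AUC / τ_w) weighted mean |
| BACKBONE | small CNN | FedAvg (sample-count weighted mean) |

Broadcast payloads round-trip through bytes and are refused if any
PERSONAL-tagged tensor is present, so the privacy partition is enforced at
the serialization boundary, not by convention.  After loading the broadcast,
each client snapshots its model (global shareable parts + its own personal
parts) as a **teacher**; during the next local epoch a distillation term
(mean-squared error on the common and interactive blocks plus T²-scaled
KL(teacher‖student) on temperature-softened class probabilities, T = 2)
anchors the student to the globally integrated knowledge.  Note the T²
prefactor keeps the gradient scale constant as T grows; the raw KL between
the softened distributions is what vanishes in the large-T limit.

Baselines share the small CNN + linear classifier architecture: FedAvg,
FedProx (gradient penalty μ(θ−θ_g), μ = 0.01), and MOON (model-contrastive
loss on backbone embeddings, τ = 0.5, weight 1.0), with formulations taken
from their original descriptions.  `local` trains the full model per center
with no communication, which makes single-client federated training reduce
to it exactly when distillation is off.  The two ablations are: `no_lmsf`
(small CNN features straight into a linear classifier; backbone aggregation
and teacher distillation remain) and `no_facm` (full LMSF model, but the
server takes a plain uniform mean of all shareable tensors with no
performance weighting and no distillation).

## Synthetic multi-center benchmark

Real multi-center cohorts of this kind are private, so the generator emulates
their structure rather than their pixels.  Each image is a textured
background plus an elliptical lesion with a radial sinusoidal margin
perturbation; the class signal lives in three lesion parameters — diameter,
margin-irregularity amplitude, and internal texture SD — drawn from
class-conditional Gaussians whose means are separated by `effect_size`
standard deviations (echoing maximum diameter / lobulation / spiculation as
clinical discriminators).  Center-specific covariate shift is applied after
lesion compositing in a fixed order: gamma → additive intensity offset →
Gaussian blur → additive Gaussian noise → clip to [0, 1].

The `lung4` preset mirrors a published four-hospital early-lung-cancer
cohort: sizes 465/198/148/115 with positive prevalences 82/465, 40/198,
27/148, 18/115, and four distinct, strong acquisition shifts (offsets
−0.12/−0.04/+0.05/+0.12, gamma 0.8/1.0/1.2/1.45, blur 0/0.6/1.0/1.5 px,
noise SD 0.02/0.05/0.08/0.12).  The positive count is exactly
`round(prevalence · n)`.  Everything is a pure function of the specs and one
master seed.  What the generator does **not** emulate: real CT texture and
anatomy, 3-D context, annotation noise, or demographic confounding — so
passing benchmarks here demonstrate that the mechanisms behave as designed
under controlled heterogeneity, not clinical performance.

The train/test split is a stratified random split (the original study's
adversarial-validation split procedure is not reproducible from public
information; stratified splitting is the documented stand-in).

## Evaluation statistics

AUC is the Mann-Whitney statistic with ties counted ½; its variance and the
paired test for two correlated AUCs use placement values (midrank
formulation).  The continuous (category-free) NRI counts strict
increases/decreases of predicted risk (ties count neither way) with the
standard binomial-difference variance; the IDI is the change in mean risk
separation between events and non-events with a paired-difference SE.
Confusion-metric intervals are Wilson score intervals (validated against
three published bracket pairs at three decimals).  Multiplicity is handled
by Benjamini-Hochberg FDR.  Decision curves use
NB(t) = TP/n − FP/n · t/(1−t).  The operating threshold is Youden-optimal on
training scores and frozen before the test set is touched.  Cross-validation
is stratified K-fold (default 5).

Cross-center feature consistency: patients at different centers have no
correspondence, so two centers are compared through their per-dimension mean
feature profiles; the Pearson correlation between two centers' d-dimensional
profiles gives one value per center pair.  Group comparisons use Welch's t
on Fisher-z transformed correlations and Cohen's d (pooled SD) on the raw
scale.  Cluster-validity indices (silhouette, Calinski-Harabasz,
Davies-Bouldin) follow the standard Euclidean definitions with degenerate
0/0 silhouette contributions counted as 0.

## Numerical engine and desk-scale choices

No GPU framework is assumed: the package ships a small vectorized
reverse-mode autograd engine over numpy (convolution via im2col), which
trains the desk-scale models in seconds per round, single-threaded and
bit-reproducibly.  The engine dtype is float64 by default; federated runs
train in float32 (`FedConfig.precision`), which halves the dominant GEMM
cost on one CPU and leaves results unchanged to about 1e-3 in AUC — runs
remain deterministic in either dtype.  Training uses momentum SGD with
global-norm gradient clipping (5.0).  Two stabilizers matter for small unnormalized CNNs: inputs
are centered, and pooled backbone features and aligned features are
layer-normalized per sample (no batch statistics, so inference is
deterministic per sample).  The gate and classifier output layers are
zero-initialized so training starts from uniform gate weights and
probability ½.  The contrast queue is cleared after each broadcast because
stored embeddings are stale under replaced parameters (configurable).

Desk-scale defaults (all configurable): images 32×32; large dim 96, small
dim 64, shared width 64, subspace dims 32, fusion dim 32; queue capacity
256; λ_align = 0.05, λ_queue = 0.02, λ_kd = 0.1; R = 15 rounds, E = 3 local
epochs, batch 16, lr 0.03, momentum 0.9; 20% of each center's training
split is held out as the local validation fold that drives the
performance-weighted interactive aggregation (τ_w = 0.1).  Because the
cross-attention runs over the batch, inference is mildly transductive:
predictions are computed in fixed chunks of 32, so scores are deterministic
given the evaluation order.  The benchmark
used by the test suite and the acceptance script runs the `lung4` preset at
scale 0.4 (sizes 186/79/59/46, proportional to the source cohort) so that
twenty complete federated runs fit in minutes of a single CPU; the auxiliary
loss weights above were calibrated on exploratory seeds disjoint from the
evaluation seeds.

## Known limitations

* The frozen large encoder is random, not pretrained; it preserves the
  structural role (stable, generic, frozen) but not the semantic strength of
  a real foundation model.  Consequently, on the synthetic benchmark the
  full framework and plain FedAvg perform comparably (mean-test-AUC
  differences of about ±0.01 across seed sets, as the benchmark suite
  measures): with no complementary information in the large branch, the
  framework's net advantage reduces to its personalization and aggregation
  effects.  A genuinely pretrained encoder plugged into the same contract is
  where the architecture is designed to pay off.
* The subspace decomposition is not identifiability-constrained: nothing
  forces "common" content out of the personal heads beyond the aggregation
  asymmetry and the shared-head averaging.
* Performance weighting uses a small local validation fold; at very small
  centers that AUC is noisy and the weights drift toward uniform.
* The evaluation battery assumes binary outcomes and probability-scale
  scores for NRI/IDI.
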