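# Methods

## The model

`fedlora` simulates cross-silo personalized federated learning for
4-class leukemia blood-smear classification (Benign, Early Pre-B, Pre-B,
Pro-B). Each client *i* holds a private image shard D_i and a composite
model

    θ^(i) = { θ_s,  θ_lora^(i),  θ_p^(i) }

where θ_s is a frozen EfficientNet feature extractor shared by every
client, θ_lora^(i) are low-rank adapters on its convolutions, and θ_p^(i)
is a private affine classifier head. Only adapter deltas are ever
communicated; the head never leaves the client, which is what makes the
scheme personalized.

### Backbone

EfficientNet-B0 and B2 are built from the published MBConv stage plan
(expand 1×1 → depthwise 3×3/5×5 → squeeze-and-excite at ratio 0.25 of the
block input → project 1×1, residual when stride 1 and channels match),
SiLU activations and batch normalization, with compound scaling
d = α^φ, w = β^φ, r = γ^φ and channel rounding to multiples of 8. The
implementation is plain numpy with explicit forward/backward passes
(im2col convolutions); B0 comes to 5,288,548 parameters and B2 to
9,109,994 in their 1000-class reference configurations — these integers
are the accounting oracle for the whole package.

A reduced `s0` variant (stem 8 channels, three MBConv blocks, 64-d
feature head, 96 px input) is built by the same machinery and is what
multi-round training simulations use; B0/B2 are exercised for
accounting, forward-identity and merge tests. This is a deliberate
problem-size choice: the simulation's purpose is to verify federation
mechanics and learning progress, which do not depend on backbone width.

Because the backbone is randomly initialized rather than pretrained, its
batch-norm statistics do not match its activations and deep activations
would shrink layer by layer. `calibrate_batchnorm` therefore sets each
layer's running statistics from one forward pass on a calibration batch
before federation starts; the statistics then join the frozen shared
state. A deployed frozen backbone would ship with matched statistics, so
this emulates the pretrained setting without external weights.

### Low-rank adapters

A targeted convolution with flattened kernel W ∈ R^{d×k}
(d = out-channels, k = in-channels·kH·kW) receives trainable
A ∈ R^{d×r}, B ∈ R^{r×k} and computes

    y = conv(W, x) + (α_lora / r) · conv(reshape(A·B), dropout(x)),

with A Gaussian (σ = 0.02), B zero — so an untrained adapter is exactly
the identity on the frozen model. The target set is every convolution
with channel-groups 1: stem, expand, SE reduce/expand, project and the
head convolution; depthwise convolutions and the classifier are
excluded. At r = 16, α_lora = 32 this yields exactly 664,368 adapter
parameters on B0 and 1,079,024 on B2, i.e. 2.53 MiB and 4.12 MiB at 4
bytes per parameter against 20.17 / 34.75 MiB for the full models —
87.44% / 88.16% reductions. On the smallest SE-reduce layers r exceeds
min(d, k); the factorization is overcomplete there, which costs a few
parameters but is kept so that a single uniform rank reproduces the
reference accounting (the injector warns about it). Adapter dropout
(default 0.1) is applied to the im2col'd input of the adapter branch
only and is disabled at evaluation, so merge/identity contracts hold
exactly in eval mode. Merging folds (α_lora/r)·A·B into W for deployment
and agrees with the adapted forward to 1e-5.

### Client training

Mini-batches are drawn with replacement using inverse-class-frequency
weights P(y_j) = (1/f_{y_j}) / Σ_k n_k/f_k, which (with f_k = n_k the
class counts) normalizes to 1/(C·f_{y_j}) and makes the expected sampled
class mix uniform. The loss is a multiclass focal loss on the true-class
softmax probability,

    L = −α (1 − p̂)^γ log p̂,   γ = 2, α = 0.25 by default,

with mean reduction and an optional per-class weight hook (off by
default); γ = 0, α = 1 recovers cross-entropy. Optimization is Adam
(default client learning rate 1e-4, batch 32, one local epoch per
round). Gradients flow through the whole network but only adapters and
the head have unfrozen parameters; a freezing audit checks the backbone
is bitwise unchanged after training. The client then uploads
Δθ_lora^(i) = θ_lora^(i) − θ_lora^(t) and nothing else.

### Server aggregation

The server averages client deltas (uniform weights by default;
n_i-proportional optional) and treats the negated mean as a
pseudo-gradient for an adaptive update without bias correction:

    g_t = −mean_delta
    m_t = β₁ m_{t−1} + (1 − β₁) g_t
    v_t = β₂ v_{t−1} + (1 − β₂) g_t²
    θ^(t+1) = θ^(t) − η · m_t / √(v_t + ε)

with η = 0.01, β₁ = 0.9, β₂ = 0.99, ε = 1e-8. The sign convention is
the one under which the global adapters move toward the client
consensus (subtracting the negated mean delta); with β₁ = 0 and a
denominator pinned by ε the step reduces to plain scaled
delta-averaging, which the tests use as a FedAvg oracle. Communication
is logged per round: uplink = Σ selected clients' delta payloads,
downlink = broadcast payload × selected clients, both in MiB
(2²⁰ bytes, 4 bytes/parameter); the symmetric round cost
2 × size × clients is reported separately.

## Synthetic smear generator

Images are procedurally drawn, not learned: a pale plasma background
with low-frequency mottle and sensor noise, plus 2–9 elliptical cells,
each a cytoplasm rim around a stained nucleus. The four classes differ
in nucleus-to-cytoplasm area ratio (0.2–0.32 up to 0.84–0.94), chromatin
texture amplitude, cell count, cell radius and stain hue — a caricature
of the benign → blast progression in which blasts are larger, more
numerous, darker-stained and have proportionally larger, coarser nuclei.
Institution-level staining variation is modelled as one fixed RGB offset
per client (uniform in ±10 intensity units), applied to the client's
shard after partitioning; channel-wise normalization statistics are
computed from the pooled training split.

The class gaps were calibrated once so that a frozen random-feature
backbone with a trained linear head separates the classes (≥ 0.9
cross-validated accuracy on `s0` features), giving federated training
signal to demonstrate progress. What passing tests show is therefore
that the federation machinery learns when linear signal exists in the
frozen features; they say nothing about the difficulty of real
cytology, where color statistics alone would not suffice and a
pretrained backbone would be doing the heavy lifting.

## Federated experiment defaults

The full-scale configuration of record is 10 clients, 20 rounds, one
local epoch, batch 32, client Adam at 1e-4, server lr 0.01, Dirichlet
label-skew partitioning at concentration 0.7 (per-class proportion
vectors over clients, largest-remainder rounding, resampled until every
client holds ≥ 20 samples), LoRA r=16/α=32/dropout 0.1, focal loss
(2.0, 0.25). The data split is a global stratified 72/8/20
train/validation/test (realized as 80/20 then a validation carve-out),
and each client's personal validation set is carved from its own shard.

The desk-scale smoke configuration (`smoke_config`) runs the same
pipeline at a size a laptop CPU handles in seconds-to-minutes: 800
synthetic images at 96 px, the `s0` backbone, rank-4/α=8 adapters, 5
rounds, client validation fraction 0.2, and a client learning rate of
1e-2 — larger than the full-scale 1e-4 because random-init features are
orders of magnitude farther from a good head than pretrained ones, so
the pretrained-regime rate would barely move in 15 optimization steps.
Its success statistic is mean personalized validation accuracy rising
from round 1 to round 5 across master seeds.

## Numerical choices and degenerate inputs

* float32 throughout the network; float64 for loss/metric reductions.
* Focal-loss probabilities are clamped at 1e-8 before the log.
* Largest-remainder rounding everywhere an integer allocation must
  conserve a total (splits, Dirichlet allocation); ties broken by
  stable sort order.
* Per-class precision/recall/F1 with a zero denominator are reported as
  0 with a warning flag rather than dropped, keeping macro averages
  defined on skewed shards; a single-cell confusion matrix (chance
  agreement 1) reports kappa 0 in the aggregate report while the
  standalone `cohens_kappa` raises.
* Multiclass MCC uses the generalized correlation form, which the tests
  verify reduces exactly to the TP/TN binary formula at C = 2; zero
  denominators give 0 by convention.
* Micro-averaged ROC/PR curves flatten the C one-vs-rest problems into
  one binary problem (scikit-learn `roc_curve` /
  `precision_recall_curve`); AP is the uninterpolated step area.
* Checkpoints and delta payloads are npz containers with a JSON header;
  round-trips are bit-exact.

## Known limitations

* No pretrained weights: absolute accuracies are far below what a
  pretrained B0/B2 reaches on real smears; only relative/mechanical
  claims are tested.
* The numpy network runs on CPU only and is ~2 orders of magnitude
  slower than a GPU framework; B0/B2 are therefore not trained for
  multiple rounds in the test suite.
* Batch-norm statistics are frozen after calibration; clients never
  adapt them (by design, but it removes one personalization channel
  real systems sometimes use).
* The stain-shift model is a global RGB offset; real scanner/stain
  variation is nonlinear and spatially structured.
* Client sampling, dropout/stragglers, secure aggregation and
  differential privacy are out of scope.
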