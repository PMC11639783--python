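# Methods

## Model

The embedding generator is a feed-forward network over NHWC float64
tensors: backbone → self-residual attention block (SRAB) ×2 → attention
block → reverse attention block → flatten → dense (Softplus) → dense
(linear) → embedding. Defaults: 200×200×3 input, SRAB filter counts
(512, 256), reverse-block filters 128, hidden width 512, embedding
dimension 256. All computation, including reverse-mode automatic
differentiation, is implemented in the package on top of numpy/scipy;
convolutions use im2col with BLAS matrix products.

### Attention arithmetic

* **Channel gate.** Per-channel global average (GAP) and max (GMP) pooled
  statistics are concatenated to a 2C vector and passed through a single
  affine layer to C logits, then a sigmoid. No bottleneck/reduction ratio
  is applied — the gate is the literal one-layer dense map. The C weights
  are reshaped to 1×1×C and multiplied elementwise into the map.
* **Spatial gate.** Per-location channel mean and max form an H×W×2 map,
  convolved with a 7×7, 1-output-channel kernel and passed through a
  sigmoid; the H×W×1 weights broadcast across channels. 7×7 is the
  standard kernel for two-channel pooled spatial gates.
* **SRAB.** Conv (3×3, stride 1, SAME padding) → batch normalization
  (ε = 1e-3, momentum 0.99) → Softplus, then channel gate, spatial gate,
  and an additive residual of the block input, 1×1-projected only when the
  input channel count differs from the conv filter count.
* **Attention block.** Channel gate then spatial gate applied directly to
  the input; no convolution preamble and no residual, so the shape is
  preserved.
* **Reverse attention block.** Conv/BN/Softplus preamble followed by a
  channel gate. As written this is a second channel attention; the
  intended "attend to what was previously downweighted" reading is
  available via `complement_gate=True`, which uses (1 − weights). The
  default is the literal form (`complement_gate=False`).

Because every gate is a sigmoid output, gate weights lie strictly in
(0, 1): gating strictly shrinks the magnitude of every nonzero entry, and
GMP ≥ GAP per channel with equality exactly for constant channels. These
invariants are enforced by property tests, and every block is checked
against straight-line loop oracles to 1e-5 on small random inputs.

### Backbones

`resnet50` is a 50-layer bottleneck residual network (stem 7×7/2 + 3×3/2
max-pool; stages of 3/4/6/3 bottleneck blocks with 64/128/256/512 base
filters, expansion 4), truncated at the final convolutional feature map
(2048 channels at 1/32 resolution). Weights are He-normal from a seeded
generator; the package ships no pretrained weights, and
`backbone_pretrained=True` raises. `tiny` is four stride-2 conv/BN/ReLU
stages (16/32/64/64 filters) for CPU-scale training; the tests and the
scaled benchmark use it at 64 px with SRAB filters (48, 48), reverse
filters 32, hidden width 128 and a 64-d embedding.

### Distances and loss

Embeddings are not L2-normalized; distances are raw Euclidean with the
square root applied (not squared distances). Inside the training graph the
summed square is clamped at 1e-24 before the square root so the gradient
stays finite when anchor and positive embeddings coincide; the public
`euclidean_distance` is exact. The triplet hinge is
max(0, d_AP − d_AN + margin) with margin 0.5 by default (margin is a
config field; it must be positive). Batch-norm in training mode uses
batch statistics over the concatenated anchor+positive+negative batch, so
weight sharing is exact by construction — the three branches are one
object.

### Training

Adam (β₁ 0.9, β₂ 0.999, ε 1e-8), default learning rate 1e-4, triplet batch
16. Triplets can be a fixed per-seed list or resampled each epoch via a
callable stream. All randomness (sampling, shuffling) flows from explicit
seeds through `numpy.random.Generator`, so a run is bit-reproducible on a
single thread. Non-finite losses abort with a diagnostic. Model state
(parameters plus batch-norm running statistics and the architecture
config) serializes to a single `.npz` archive; a round trip reproduces
embeddings exactly.

## Data pipeline

Metadata follows the NIH-style CSV dialect (`Image Index`, `Patient ID`;
a column mapping adapts other layouts). Patients with fewer than two
radiographs are excluded — they can serve neither as anchor-positive pairs
nor as evaluable queries. Images are read as 8-bit PNG, converted to RGB
(grayscale planes replicated), resized to the network input with bilinear
anti-aliased interpolation, and scaled to [0, 1]. Triplet sampling takes,
per pass over the shuffled patients, one anchor per patient, a positive
uniformly from the patient's remaining images, and a negative uniformly
from a uniformly chosen other patient's images; every draw is replayable
from its seed.

## Synthetic phantom cohort

The generator emulates the statistical structure the method assumes:
identity-stable anatomy plus acquisition variation. Each identity is a
parametric geometry — thorax ellipse semi-axes (0.27–0.38 and 0.31–0.42 of
the frame), 7–10 ribs with per-identity spacing (0.055–0.080) and
curvature (0.10–0.40), cardiac silhouette width (0.22–0.42 of the thorax
half-width), clavicle angle (5–22°), spine offset (±0.03) — rendered as
bright bands/ellipses over darker lung fields. Each acquisition applies
brightness jitter (±0.08), contrast jitter (±10 %), rotation (±3°),
translation (±2 % of the frame) and additive Gaussian noise (σ = 0.03),
all seeded. These ranges were fixed once as a plausible caricature of
patient-positioning and exposure variation.

What the phantoms do **not** model: real radiographic texture, projection
physics, pathology, sex/age anatomy covariates, scanner differences, or
longitudinal anatomical change. Passing the scaled benchmark therefore
shows that the implementation can learn identity-stable structure under
acquisition nuisance — not that it reaches any particular accuracy on
clinical data.

## Evaluation protocol

Identification is closed-set: every image of a patient with ≥ 2 stored
images is a query against the gallery of all *other* images (self-match
excluded, since it trivializes the metric); top-1 accuracy and top-5 hit
rate are the fractions of queries whose rank-1 match, respectively any
top-5 match, shares the query's patient. Ties in distance break
lexicographically by image id. Verification samples balanced labeled
pairs, calibrates the threshold on half of them (accuracy-maximizing
midpoint of sorted distances; ties resolve to the smallest threshold; the
equal-error-rate point is also computed) and reports accuracy, precision
and recall on the held-out half with the strict rule same ⇔ distance <
threshold.

## Scaled benchmark

`sran.benchmark.run_identity_benchmark` renders 20 identities × 5 images
at 64 px, trains the tiny model for 30 epochs of 200 freshly resampled
triplets (batch 16, Adam lr 1e-3 — a per-epoch resample keeps the hinge
active once a fixed list is satisfied, which matters at this cohort size),
and evaluates the trained model and its identically initialized untrained
twin under the protocol above. The run takes a few minutes on one CPU
core. The expected qualitative outcome is trained ≫ untrained on both
identification and verification.

## Numerical choices and edge cases

* float64 throughout; deterministic given seeds and a fixed thread count.
* Batch-norm ε = 1e-3; analytic zero-parameter tests fix running mean 0 /
  variance 1 so the normalization is an ε-scaled identity (tolerance 1e-4).
* Max reductions route gradients equally across exact ties.
* SAME padding follows the ceil-division convention (extra pixel on the
  bottom/right).
* Degenerate inputs raise: empty feature maps, channel-count mismatches,
  non-finite inputs (and non-finite SRAB intermediates name the failing
  stage), single-patient triplet sampling, single-class threshold
  calibration, galleries smaller than k (warn + truncate).

## Known limitations

* No GPU path and no minibatch parallelism; the full-scale backbone is
  practical for inference and small fine-tuning runs only.
* No hard- or semi-hard negative mining; negatives are uniform draws.
* The reverse attention block's complement mode is provided but untrained
  models make no use of its intended semantics by default.
* Closed-set evaluation only; no open-set rejection.
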