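# Methods

## The two prediction tasks

Phosphorylation of serine, threonine or tyrosine residues can switch
protein–protein interactions (PPIs) on or off. `phosfx` models this in
two consecutive binary classification steps, both from sequence alone:

1. **Functional-site identification.** Given a protein and a candidate
   S/T/Y position `p`, predict whether phosphorylation at `p` has a
   functional effect (`F1 : p → s ∈ {0, 1}`).
2. **Regulatory-effect classification.** Given a protein pair `(A, B)`
   and a functional site `p` on `A`, predict whether phosphorylation at
   `p` enhances (`y = 1`) or inhibits (`y = 0`) the A–B interaction
   (`F2 : (A, B, p) → y`).

Residues are represented by per-residue embeddings from a protein
language model (PLM): ProtBERT (D = 1024) or ESM-2 (D = 1280), exposed
as optional adapters, or a deterministic mock backend for development
and testing. Embedding width `D` is carried in the data everywhere;
nothing downstream hard-codes it.

## Feature extraction

- **Global features** are the full `L × D` embedding of a protein.
- **Local features** are a fixed window of 15 residues either side of
  the candidate site (31 positions). Out-of-range slots carry the `*`
  pad symbol; its embedding row is the zero vector and a binary mask
  marks it, so pads are inert under sum pooling and receive zero
  attention weight. Windows are *sliced out of the full-sequence
  embedding* (embed first, cut second), so the local rows retain the
  long-range context the PLM put into them.

## Model architectures

All models are built on a small reverse-mode automatic-differentiation
engine over numpy float64 arrays (`phosfx.nn`): broadcasted arithmetic,
batched matmul, an im2col 1-D convolution, fused softmax and
row-standardisation primitives, exact-erf GELU, and multi-head
scaled-dot-product attention with key masking.

### Site classifier

`SiteModel` reads the whole sequence end to end (no windowing in this
task; convolutions supply the local receptive field):

- linear projection `D → 64`;
- 3 convolutional blocks (kernel 7, same padding): each is
  `x + LayerNorm(GELU(conv(x)))` — post-norm, residual after the
  normalisation;
- an attention decoder whose single query is the *encoded row of the
  target residue*: per block, self-attention over the length-1 query
  stream, then cross-attention against all encoder rows (8 heads,
  d_k = 8), each followed by residual + LayerNorm;
- a three-layer classifier `64 → 64 → 64 → 2` with GELU between, and a
  softmax pair output. Ties at probability 0.5 predict class 0
  (non-functional), the conservative call.

A structural property worth knowing: with a length-1 query stream the
self-attention softmax is constant, so the decoder's self-attention
query/key projections receive exactly zero gradient. This follows from
the single-target-query design; the value/output projections remain
live, and the gradient-flow test checks every other parameter.

### Effect submodels

Both consume the same three streams — the 31-window of `A` centred on
the site, global `A`, global `B` — and emit an
(inhibition, enhancement) pair.

**Attention-gated CNN.** Each stream passes a convolutional branch
(kernel 7 → GELU → LayerNorm → masked *sum* pooling) to a 64-vector.
A scalar gate `α = σ(W[h_l; h_gA; h_gB] + b)` weights them as
`h = α·h_l + α·h_gA + (1−α)·h_gB`. The coefficients deliberately do
not sum to one — this is the model's printed definition — and a config
switch (`normalize_fusion`) offers the convex variant `h / (1+α)` for
ablation. The classifier is three linear layers with GELU and GroupNorm
(8 groups of 8 channels) after each hidden layer.

**Cross-attention Transformer.** Every stream is projected to 64 dims;
the two global streams are refined by a conv + gated-linear-unit
residual block, `LayerNorm(x + GLU(conv(x)))` with
`GLU(z) = (zW₁+b₁) ⊙ σ(zW₂+b₂)`. Their encoded rows are concatenated
(`L_A + L_B` rows) as the cross-attention memory. The decoder runs
exactly 3 blocks over the 31 local positions: pad-masked multi-head
self-attention, cross-attention into the memory, and a position-wise
feed-forward network, each with residual + LayerNorm. The decoded
window is masked-mean-pooled (scale independent of pad count; a
centre-row readout is available via `decoder_readout="center"`) and
classified by three linear layers.

### Ensemble

The two submodels are fused per pair by one of three voters:

- **soft** (default): elementwise mean of the probability pairs;
- **hard**: each submodel casts its thresholded label (ties at the
  threshold vote 0); a 1–1 split falls back to the soft-vote label,
  since a two-voter majority is otherwise undefined;
- **max-confidence**: the pair of the submodel whose larger class
  probability is higher; exact ties fall back to soft voting.

## Training

- Losses: plain cross-entropy for the balanced site task; a
  batch-weighted cross-entropy for the imbalanced effect task, with
  per-class weights `w_c = n_batch / (2 n_c)` recomputed from each
  batch's label counts and the loss normalised by the summed sample
  weights. On any balanced batch this reduces exactly to plain
  cross-entropy — the property that pins the definition.
- Optimiser: RAdam (variance-rectified Adam) wrapped in Lookahead
  (k = 5, α = 0.5, the standard values). Library defaults follow the
  reference configuration: learning rate 5e-4, batch size 128, kernel
  size 7, 8 heads, window 31.
- Epoch counts are always explicit in `TrainConfig`; with a validation
  split the best-validation-loss parameters are returned, otherwise the
  final ones. Training is deterministic given the config (seeded
  shuffling and initialisation, single-threaded).

For the scaled synthetic benchmark (below) the experiment configs use
batch size 32 — at 320 training samples the default batch of 128 yields
only 3 optimiser steps per epoch — and learning rate 1e-3 for the
effect models, the most stable of the rates swept; the site task keeps
5e-4.

## Synthetic data

The generator (`phosfx.synthetic`) emulates the statistical shape of
the two curated tasks without any downloads:

- i.i.d. uniform sequences over the 20 standard residues (default: 200
  proteins of 50–100 residues, each with ≥ 3 S/T/Y);
- a **site table** whose candidate set is every S/T/Y position, with a
  site functional iff the literal motif `RR` occupies offsets (−3, −2)
  upstream; classes balanced exactly (residue-stratified negative
  sampling), default 400 records;
- a **pair table** (default 400 records, ~70/30
  enhancement/inhibition) whose label is
  `enhancement ⇔ motif(A, p) XOR inhibitor-trigram(B)`, the trigram
  (`DED`) planted in the first 20 residues of a sixth of the pool — so
  the label provably depends on *both* proteins and a partner-blind
  predictor is capped at `1 − 1/6 ≈ 0.833` accuracy (see
  `a_only_bayes_accuracy`);
- optional symmetric label noise (`noise_rate`).

Because the motif occurs spontaneously only ~1/400 per candidate, the
generator *plants* it (and the trigram) by overwriting residues; labels
are always computed from the final sequences, so they are exactly
rule-consistent at `noise_rate = 0`. The two tasks use disjoint protein
pools (first half / second half) so their planted signals cannot
contaminate each other's labels, and pair slots within a protein are
kept ≥ 4 positions apart so plants never overwrite each other.

The mock embedding backend maps each residue to the normalised sum of
three hashed slot vectors (previous, centre, next letter). It is
deterministic, context-sensitive, unit-variance, and — like real PLM
embeddings — leaves residue identity linearly decodable per row, which
is what makes the planted motif learnable in principle. What it does
*not* model: biochemical similarity between residues, long-range
context beyond the trigram, or real phospho-motif biology; passing the
synthetic benchmark therefore demonstrates that the pipeline and
optimisation work, not that the models would reach any particular
accuracy on curated data.

## The scaled benchmark and a known limitation

`phosfx.pipeline.run_benchmark` (also run by `scripts/acceptance.py`)
trains everything on the default synthetic conditions with mock D = 32
and reports held-out metrics on stratified 20% splits. Problem sizes
were chosen so the whole benchmark completes in minutes on one CPU.

Measured behaviour at these sizes:

- the **site classifier generalises** (held-out accuracy ≈ 0.91, AUROC
  ≈ 0.97 at seed 1): its readout is localised at the target residue,
  whose convolutional receptive field covers the motif offsets;
- the **effect submodels memorise instead of generalising** (training
  accuracy 1.0, held-out AUROC ≈ 0.5). This is an architectural
  sample-efficiency limit, not a training bug: the planted signal is
  perfectly linearly decodable at a single window row, but after the
  sum/mean pooling both architectures apply, its per-channel
  signal-to-noise ratio falls below one standard deviation (2 signal
  rows against ~29 nuisance rows of unit-variance embeddings), and
  even an L2-regularised logistic readout on the pooled features tops
  out near the majority rate. Sweeps over learning rate, model width,
  epoch count, early stopping and the centre-row readout did not
  change the plateau. With roughly an order of magnitude more pairs —
  the scale of the curated training table — and real PLM embeddings,
  the pooled architectures have proportionally more signal to work
  with; at the reduced benchmark scale they do not reach the site
  model's level, and the benchmark reports exactly what they achieve.

## Numerical and convention notes

- GELU uses the exact error-function form `x·Φ(x)`, not the tanh
  approximation; gradients use `Φ(x) + x·φ(x)`.
- Probabilities inside losses are clamped at 1e-12 before the log.
- Threshold conventions: metrics count `score ≥ threshold` as a
  positive prediction; the voters and `Prediction` break exact ties
  *toward class 0*. Both conventions are covered by tests.
- AUPR is the step-wise average-precision estimator (no trapezoidal
  interpolation); AUROC is the Mann–Whitney statistic with ties at ½.
- Precision/recall/F1 are 0 when their denominator is 0; MCC is 0 when
  any confusion-matrix marginal is 0.
- Degenerate inputs: empty masks, all-pad windows, all-masked attention
  keys, single-class label vectors and truncated embeddings that no
  longer cover a site all raise informative errors rather than
  returning silent values.
- Sequences longer than a backend's context window are truncated to
  the N-terminal prefix with a warning; sites beyond the truncation
  point fail loudly downstream.
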