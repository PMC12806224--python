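# Methods

## Model

The language model is a causal character-level predictor over a 28-token
amino-acid vocabulary: the 20 standard residues in a fixed order
(D,N,E,K,V,Y,A,Q,M,I,T,L,R,F,G,C,S,P,H,W), five extended codes for rare or
ambiguous residues (X,B,Z,U,O — the IUPAC extended set), and pad/sep/unk.
Input is upper-cased; characters outside the 25 residue codes map to unk.
No beginning-of-sequence token is used: position i's logits predict token
i+1, so a length-L sequence contributes L−1 predictions and the first
residue is never scored.

Each of the stacked mixing layers is a pre-normalization residual block —
`x + Mixer(LN(x))` then `x + FFN(LN(x))` — with a final layer normalization
and a decoding head weight-tied to the embedding table. The feed-forward
activation is GELU. There is no learned position table: position enters only
through the mixer.

### The Hyena operator

The mixer computes the order-N recurrence

    y = x_N . (h_N * ( ... x_1 . (h_1 * v) ... ))

* **Projections.** One dense layer maps the input (L×D) to N+1 streams,
  followed by a depthwise *causal* short convolution (width 3; the smallest
  nontrivial local mixer). All downstream state at position t therefore
  depends only on positions ≤ t.
* **Gating** is element-wise multiplication, equivalently the action of a
  diagonal matrix per channel.
* **Long convolution** by a causal filter h equals multiplication by the
  lower-triangular Toeplitz matrix (T_h)_ij = h(i−j). It is evaluated by
  real FFT after zero-padding to the next power of two ≥ 2L, so the circular
  convolution realizes the linear causal one exactly; no L×L matrix is ever
  materialized on this path. An explicit O(L²) Toeplitz implementation is
  kept as the exactness oracle, and the test-suite requires agreement to
  1e−5 relative error in double precision for L up to 1024.
* **Implicit filters.** Filter taps are produced by a small network of the
  *time index only*: 8 sinusoidal features of t/L, two hidden layers of
  width 32 with sine activation, a linear map to N·D channels, and a
  learnable per-channel exponential decay window softplus(r)·5·t/L that
  localizes the filters at initialization. Parameter count is thus
  independent of L. Filters are treated as data-independent: this is the
  only reading consistent with the Toeplitz form h(i−j), so no
  embedding-conditioned filter scheme is implemented.

With the default configuration — 2 layers, order N=2, embedding 256,
feed-forward 1024, vocabulary 28, maximum length 1024, tied head — the model
has 1,629,312 trainable parameters (1.6 M). Head tying and the absence of a
position table are required to land on this budget.

### Baselines

The attention decoders share the tokenizer, block layout, tied head and
training loop, swapping the mixer for multi-head causal self-attention with
1/√d_head score scaling. Attention scores are causally masked — an unmasked
decoder cannot train a next-token objective — and position enters through
parameter-free rotary embeddings: a learned position table of
size max_len×D would push the 8-layer/512-wide configuration to ≈25.5 M,
off its 25.2 M budget. Head counts (4 tiny, 8 base) do not change parameter
counts. Exact totals: tiny (2 layers, 256/1024) = 1,587,200; base (8 layers,
512/2048, max length 512) = 25,234,432.

The CNN regressor stacks 35 residual blocks (conv → ReLU → conv + identity,
ReLU on the sum) of 256 filters, kernel 9, dilation 2, over a kernel-9
embedding convolution from the 25 residue channels, with global average
pooling and a scalar head: 41,363,713 parameters (41 M). Block structure,
activation and input embedding are pinned here as conventional choices; only
the block/filter/kernel/dilation numbers and the ≈41 M total are fixed
externally.

## Training

* **Objective**: mean cross-entropy over predicted, non-pad positions.
  Perplexity is PPL = e^H with H that same mean; the identity is enforced to
  1e−9 relative in the report type.
* **Optimizer**: Adam (β₁=0.9, β₂=0.999, ε=1e−8), no weight decay, global
  gradient-norm clipping at 1.0, cosine learning-rate decay with optional
  linear warmup. The reference full-scale schedule is initial lr 6e−4,
  batch 256, ~30k steps; desk-scale runs (below) use shorter schedules with
  proportionally higher lr (3e−3) and batch 32.
* **Batching**: sequences are right-padded per batch; pad targets are masked
  out of the loss; no sequence packing (the sep token is reserved but
  unused), so no cross-sequence leakage. Validation is a seeded 1% split by
  default. Runs are deterministic given the config seed (single-threaded
  numpy, float64).
* **Fine-tuning**: a fresh linear decoder D→K on top of the backbone;
  residue-level tasks apply it per position, protein-level tasks after
  arithmetic mean pooling over non-pad positions. Regression uses K=1 and
  the raw scalar with MSE. The backbone is updated by default
  (`freeze_backbone` gives the frozen-feature variant). Defaults: Adam,
  lr 1e−4 with cosine decay, early stopping on a validation slice
  (patience 5). The reference experiments use task-specific budgets listed
  below; for the out-of-distribution landscape task early stopping is
  disabled, because the in-distribution validation loss is uninformative
  about ranking quality under the distance shift, and the full cosine
  schedule is run to convergence.

## Numerical engine

No GPU framework is used: `autograd.py` implements a tape-based reverse-mode
engine over float64 numpy arrays with analytically derived backward passes
for dense algebra, softmax/cross-entropy, layer normalization, embedding
lookup, depthwise and dilated convolutions, the FFT causal convolution
(gradients are FFT correlations) and the rotary rotation. All gradient
formulas are verified against central finite differences in the test-suite.
Double precision keeps the operator-exactness comparisons meaningful; the
models at desk scale train in minutes on one core.

## Synthetic data: what it emulates and what it does not

The generators provide *calibrated* stand-ins for the pretraining corpus and
the downstream benchmark suite, with ground truth that real data cannot
offer:

* **Markov proteomes.** First-order (or memoryless) chains over the 20
  standard residues; the entropy rate H* = −Σ_s π(s) Σ_t P(s,t) log P(s,t)
  is computed exactly from the stationary distribution, so e^{H*} is the
  optimal held-out perplexity of *any* predictor. The reference source is a
  "preferred successor" chain (each residue puts mass 0.5 on one designated
  successor, the rest uniform): H* = 2.1654 nats, optimal PPL 8.72 —
  structured enough that learning is visible, easy enough that a small model
  converges in a few hundred steps. Real proteomes have long-range and
  family structure that a first-order chain lacks; passing the recovery test
  shows the pipeline optimizes its objective to the information-theoretic
  floor, not that it models real proteins.
* **Motif tasks.** Binary labels from an implanted degenerate motif
  (8 positions, 2 allowed residues per position) on uniform background,
  lengths 40–80, with preset positive-class fractions mirroring the
  benchmark suite's imbalances (0.7 ≈ 3:7 neuropeptide-cleavage-like,
  0.8 ≈ 2:8 signal-peptide-like, 0.5 balanced, 0.99 near-degenerate
  disorder-like). The generator is calibrated so a converged small model
  reaches AUROC ≈ 0.95 at protein resolution — learnable but not trivial.
  Residue resolution labels in-motif positions; note a causal model can
  only detect a motif a few positions into it, which bounds residue recall
  below 1 by construction.
* **Fitness landscapes.** A random parent (length 60); per-site/per-residue
  additive effects N(−0.35, 0.25²) (parent residue ≡ 0), 10 random site
  pairs with N(0, 0.3²) epistatic interactions, observation noise
  N(0, 0.1²), baseline 3.8. Train split = Hamming distance 1–3 from parent,
  test split = distance 4–15; because effects are mostly deleterious the
  test labels shift strongly downward, reproducing qualitatively the
  train/test location shift of mutational-scan benchmarks. In the
  zero-epistasis, zero-noise limit the labels are exactly linear in one-hot
  mutation indicators (asserted by a least-squares test). No numeric claim
  from any real landscape is asserted.

All generators are bit-reproducible from (config, seed).

## Reference experiment sizes

The shared battery (`prothyena.experiments`, run by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) uses sizes chosen so
each property is measured with margin while the whole battery stays at
minutes on one core:

* entropy-rate recovery: D=64/ffn 128 model, 5,000 training and 300 held-out
  sequences of length 60–100, 500 steps, batch 32, lr 3e−3 cosine. The
  held-out PPL lands within a fraction of a percent of e^{H*}; the
  acceptance band is [0.98, 1.05]×e^{H*} (finite-sample fluctuation below,
  convergence above).
* matched-budget comparison: Hyena D=48/ffn 96 (49,440 params) vs attention
  D=48/ffn 160 (51,776 params — the baseline gets the slightly larger
  budget), identical data, 400 steps, same seed policy. Both converge near
  the entropy floor, so the ratio of held-out perplexities sits near 1.
* fine-tuning: motif protein-level n=2,500 (≈2,000 train / 500 test),
  backbone D=32, 12 epochs lr 1e−3; residue-level n=1,200, 6 epochs
  lr 3e−3; landscape 2,000 train / 500 test, 30 epochs lr 1e−3 without
  early stopping (see above).

## Known limitations

* Filters are functions of the time index only; no data-controlled filter
  variant is provided.
* The Student-t regression loss is defined here as the log-kernel of a
  standardized Student-t, mean of ((ν+1)/2)·log(1+r²/ν) with ν=1 by
  default; other conventions exist, and ν and the normalization are
  configurable.
* Macro-F1 counts classes absent from labels and predictions as 0; MCC
  returns 0 on degenerate marginals; AUROC is the exact rank-sum statistic
  (ties ½), AUPRC is average precision without interpolation.
* Greedy decoding only; no sampling or generation utilities.
* Training is single-process and CPU-bound by design; wall-clock and memory
  comparisons between architectures are out of scope.
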