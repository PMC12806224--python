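# prothyena

A character-level autoregressive protein language model whose sequence mixer
replaces self-attention with the **Hyena operator** — alternating causal long
convolutions and element-wise gating — together with the attention and CNN
baselines it is compared against, pretraining and fine-tuning machinery, a
full metric suite, and seeded synthetic-data generators with analytically
known optima. Everything runs on one CPU core: the neural models are built on
a small reverse-mode autodiff engine over numpy arrays included in the
package.

## Who this is for

Researchers who want a compact, fully inspectable implementation of
subquadratic protein language modeling: the operator algebra, its FFT
evaluation with an exact quadratic oracle, the training objectives, and the
downstream-task plumbing (residue- and protein-level classification and
regression) — testable end to end without downloading any protein corpus.

## The model

A protein sequence `a_1..a_L` is tokenized one amino acid per token over a
28-symbol vocabulary (20 standard residues in a fixed order, 5 rare/ambiguous
codes, pad/sep/unk). The language model maximizes

```
P(a_1, ..., a_L) = prod_i P(a_i | a_1, ..., a_{i-1})
```

Each of the 2 mixing layers applies an order-N Hyena operator (default N=2):

```
y = x_N . (h_N * ( ... x_1 . (h_1 * v) ... ))
```

where `v, x_1..x_N` are projections of the input (dense layer + depthwise
causal short convolution), `.` is element-wise gating (a diagonal matrix
`D_x` per position), and `*` is causal long convolution: multiplication by
the lower-triangular Toeplitz matrix `(T_h)_ij = h(i-j)`. For N=2 this is
the matrix form `y = D_x2 T_h2 D_x1 T_h1 v`. Filters are *implicit*:
`h_t = gamma(theta(t))`, a small sine-activated network of the time index
with a learnable exponential decay window, so the parameter count is
independent of sequence length. Convolutions are evaluated in O(L log L) by
FFT and verified against the explicit O(L^2) Toeplitz product.

Model quality is measured by perplexity `PPL = e^H`, with `H` the mean
negative log conditional probability per predicted position: a perfect
predictor scores 1; uniform guessing over the 20 standard residues scores 20.

The default configuration (2 layers, embedding 256, feed-forward 1024, tied
decoding head, max length 1024) has 1.6 M trainable parameters; the
attention baselines land at 1.6 M (tiny) and 25.2 M (base), and the dilated
residual CNN regressor at 41 M.

## Worked example

```python
import numpy as np
from prothyena import (MarkovSource, markov_proteome, entropy_rate,
                       ModelConfig, build_model, desk_scale_config,
                       pretrain, perplexity)
from prothyena.pretrain import encode_corpus

# a first-order Markov "proteome" whose optimal perplexity is known exactly
source = MarkovSource.preferred_successor(stay=0.5, seed=0)
train, h_star = markov_proteome(source, 5000, (60, 100), seed=2)
held, _ = markov_proteome(source, 300, (60, 100), seed=3)
print(f"entropy rate H* = {h_star:.4f} nats -> optimal PPL = "
      f"{np.exp(h_star):.4f}")

model = build_model(ModelConfig(n_layers=2, embed_dim=64, ffn_dim=128,
                                max_len=128), seed=0)
cfg = desk_scale_config(total_steps=500, batch_size=32, lr=0.003, seed=0)
model, log = pretrain(model, [s for _, s in train], cfg,
                      val_sequences=[s for _, s in held])
rep = perplexity(model, encode_corpus([s for _, s in held]))
print(f"held-out PPL = {rep.ppl:.4f} ({rep.ppl / np.exp(h_star):.4f} x "
      f"optimal)")
```

prints (a few minutes on one core):

```
entropy rate H* = 2.1654 nats -> optimal PPL = 8.7178
held-out PPL = 8.7146 (0.9996 x optimal)
```

i.e. the pretrained model's held-out perplexity reaches the source's
entropy-rate bound `e^{H*}` to within a fraction of a percent — it has
recovered the generating conditional distribution. (The ratio may sit
slightly below 1 on a finite held-out sample; systematically beating the
bound is impossible, which the test-suite asserts.)

There is also a CLI:

```
prothyena simulate corpus --n 1000 --seed 7 --out runs/corpus
prothyena pretrain --fasta runs/corpus/corpus.fasta --steps 500 --out runs/lm
prothyena perplexity --model runs/lm/model.h5 --fasta runs/corpus/corpus.fasta
prothyena params --preset hyena
```

## Layout

- `src/prothyena/autograd.py`, `nn.py` — numpy reverse-mode autodiff engine
  and layer/optimizer primitives
- `vocab.py` — amino-acid vocabulary and tokenization
- `hyena.py` — the operator: projections, implicit filters, FFT causal
  convolution, Toeplitz oracle
- `model.py`, `baselines.py` — the Hyena LM, attention decoders, CNN
  regressor
- `pretrain.py`, `finetune.py` — objectives, schedules, training loops
- `metrics.py` — MCC, macro-F1, AUROC, AUPRC, Spearman, regression losses
- `synthetic.py` — Markov corpora, motif tasks, fitness landscapes
- `io.py`, `cli.py` — FASTA/TSV/YAML/HDF5 formats and the command line

See `docs/methods.md` for modeling assumptions, default parameters, and the
design decisions behind the synthetic generators.
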