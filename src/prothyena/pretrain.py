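"""Autoregressive pretraining and perplexity evaluation.

The objective maximizes prod_i P(a_i | a_1..a_{i-1}) over amino-acid tokens:
logits at position i score token i+1, so a sequence of length L contributes
L-1 predictions (no beginning-of-sequence token; the first residue is never
predicted). Perplexity is PPL = e^H with H the mean negative log conditional
probability per predicted, non-pad position — so a perfect predictor scores
1 and a uniform guess over the 20 standard residues scores 20.

Optimization is Adam with cosine learning-rate decay and global-norm
gradient clipping; runs are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor
from .nn import Adam, clip_global_norm
from .vocab import build_vocabulary, encode

__all__ = ["TrainConfig", "CosineSchedule", "cosine_lr", "nll_loss",
           "PerplexityReport", "perplexity", "pretrain"]


@dataclass
class CosineSchedule:
    initial_lr: float = 0.0006
    min_lr: float = 0.0
    total_steps: int = 30000
    warmup_steps: int = 0


def cosine_lr(step: int, schedule: CosineSchedule) -> float:
    """Warmup (linear) then cosine decay from initial_lr to min_lr."""
    if step < 0:
        raise ValueError("step must be nonnegative")
    s = schedule
    if s.warmup_steps > 0 and step < s.warmup_steps:
        return s.initial_lr * (step + 1) / s.warmup_steps
    span = max(s.total_steps - s.warmup_steps, 1)
    progress = min((step - s.warmup_steps) / span, 1.0)
    return s.min_lr + 0.5 * (s.initial_lr - s.min_lr) * \
        (1.0 + np.cos(np.pi * progress))


@dataclass
class TrainConfig:
    batch_size: int = 256
    max_len: int = 1024
    total_steps: int = 30000
    schedule: CosineSchedule = field(default_factory=CosineSchedule)
    grad_clip: float = 1.0
    val_fraction: float = 0.01
    seed: int = 0
    log_every: int = 50

    def to_dict(self) -> dict:
        return asdict(self)


def desk_scale_config(total_steps: int = 1000, batch_size: int = 32,
                      lr: float = 0.003, max_len: int = 1024,
                      seed: int = 0, **kw) -> TrainConfig:
    """A small-budget configuration for CPU-scale experiments."""
    return TrainConfig(batch_size=batch_size, max_len=max_len,
                       total_steps=total_steps,
                       schedule=CosineSchedule(initial_lr=lr,
                                               total_steps=total_steps,
                                               warmup_steps=min(
                                                   50, total_steps // 10)),
                       seed=seed, **kw)


# ------------------------------------------------------------------ objective

def nll_loss(logits: np.ndarray, tokens: np.ndarray,
             pad_id: int | None = None) -> float:
    """Mean negative log conditional probability over predicted positions.

    ``logits``: (B, L, V) or (L, V); position i scores token i+1. Positions
    whose *target* is pad are excluded. Raises if nothing is predicted.
    """
    logits = np.asarray(logits, dtype=np.float64)
    tokens = np.asarray(tokens)
    if logits.ndim == 2:
        logits, tokens = logits[None], tokens[None]
    pred_logits = logits[:, :-1, :]
    targets = tokens[:, 1:]
    mask = np.ones_like(targets, dtype=np.float64) if pad_id is None \
        else (targets != pad_id).astype(np.float64)
    if mask.sum() == 0:
        raise ValueError("no non-pad positions to predict")
    zmax = pred_logits.max(axis=-1, keepdims=True)
    z = pred_logits - zmax
    lse = np.log(np.exp(z).sum(axis=-1)) + zmax[..., 0]
    picked = np.take_along_axis(pred_logits, targets[..., None], axis=-1)[..., 0]
    return float(((lse - picked) * mask).sum() / mask.sum())


@dataclass(frozen=True)
class PerplexityReport:
    H: float                 # mean NLL, nats per predicted position
    ppl: float               # e^H
    n_positions: int

    def __post_init__(self):
        if not np.isclose(self.ppl, np.exp(self.H), rtol=1e-9):
            raise ValueError("PPL must equal e^H")


def perplexity(model, corpus, pad_id: int | None = None,
               batch_size: int = 32) -> PerplexityReport:
    """Corpus-level perplexity of a language model.

    ``corpus`` is a list of integer id arrays (each length >= 2). H is the
    total NLL over all predicted positions divided by their count.
    """
    seqs = [np.asarray(getattr(s, "ids", s)) for s in corpus]
    seqs = [s for s in seqs if s.size >= 2]
    if not seqs:
        raise ValueError("perplexity requires a nonempty corpus")
    pad = pad_id if pad_id is not None else -1
    total_nll, total_n = 0.0, 0
    for start in range(0, len(seqs), batch_size):
        chunk = seqs[start:start + batch_size]
        L = max(len(s) for s in chunk)
        ids = np.full((len(chunk), L), 0, dtype=np.int64)
        mask = np.zeros((len(chunk), L), dtype=np.float64)
        for i, s in enumerate(chunk):
            ids[i, :len(s)] = s
            mask[i, :len(s)] = 1.0
        logits = model.forward(ids).data
        targets = ids[:, 1:]
        m = mask[:, 1:] * (targets != pad)
        pred = logits[:, :-1, :]
        zmax = pred.max(axis=-1, keepdims=True)
        lse = np.log(np.exp(pred - zmax).sum(axis=-1)) + zmax[..., 0]
        picked = np.take_along_axis(pred, targets[..., None], axis=-1)[..., 0]
        total_nll += float(((lse - picked) * m).sum())
        total_n += int(m.sum())
    H = total_nll / total_n
    return PerplexityReport(H=H, ppl=float(np.exp(H)), n_positions=total_n)


# ------------------------------------------------------------------- training

def encode_corpus(sequences, max_len: int = 1024) -> list:
    """Encode raw amino-acid strings, right-truncating overlong ones."""
    vocab = build_vocabulary()
    return [encode(s, vocab, max_len=max_len).ids for s in sequences]


def pretrain(model, sequences, config: TrainConfig | None = None,
             val_sequences=None):
    """Train ``model`` autoregressively on amino-acid strings or id arrays.

    Returns (model, log) where log is a list of dicts with step, loss, lr
    and (at log points) validation perplexity. Deterministic given
    ``config.seed``.
    """
    config = config or TrainConfig()
    if len(sequences) == 0:
        raise ValueError("empty training corpus")
    ids = [np.asarray(getattr(s, "ids", s)) if not isinstance(s, str)
           else encode(s, max_len=config.max_len).ids for s in sequences]
    rng = np.random.default_rng(config.seed)
    if val_sequences is None:
        n_val = max(1, int(len(ids) * config.val_fraction))
        perm = rng.permutation(len(ids))
        val_ids = [ids[i] for i in perm[:n_val]]
        train_ids = [ids[i] for i in perm[n_val:]]
    else:
        train_ids = ids
        val_ids = [np.asarray(getattr(s, "ids", s)) if not isinstance(s, str)
                   else encode(s, max_len=config.max_len).ids
                   for s in val_sequences]
    vocab = build_vocabulary()
    pad = vocab.pad_id
    opt = Adam(model.parameters(), lr=config.schedule.initial_lr)
    log = []
    for step in range(config.total_steps):
        idx = rng.choice(len(train_ids),
                         size=min(config.batch_size, len(train_ids)),
                         replace=len(train_ids) < config.batch_size)
        chunk = [train_ids[i] for i in idx]
        L = max(len(s) for s in chunk)
        batch = np.full((len(chunk), L), pad, dtype=np.int64)
        for i, s in enumerate(chunk):
            batch[i, :len(s)] = s
        logits = model.forward(batch)
        targets = batch[:, 1:]
        mask = (targets != pad).astype(np.float64)
        # also mask positions whose input is pad (first pad predicts nothing)
        loss = logits[:, :-1, :].cross_entropy(targets, mask)
        model.zero_grad()
        loss.backward()
        clip_global_norm(opt.params, config.grad_clip)
        lr = cosine_lr(step, config.schedule)
        opt.step(lr=lr)
        entry = {"step": step, "loss": float(loss.data), "lr": lr}
        if step % config.log_every == 0 or step == config.total_steps - 1:
            entry["val_ppl"] = perplexity(model, val_ids, pad_id=pad).ppl
        log.append(entry)
    return model, log
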