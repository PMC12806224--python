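"""The ProtHyena language model.

Embedding -> n_layers pre-norm blocks (Hyena operator + feed-forward, each
with a residual connection) -> final layer normalization -> decoding head.
The head is weight-tied to the embedding table and there is no learned
positional table: the implicit long filters carry position, which keeps the
default configuration at the 1.6 M trainable-parameter budget.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor
from .nn import Module, Linear, Embedding, LayerNorm
from .hyena import HyenaOperator

__all__ = ["ModelConfig", "HyenaBlock", "ProtHyenaLM", "build_model",
           "count_parameters", "params_in_millions"]


@dataclass
class ModelConfig:
    n_layers: int = 2
    embed_dim: int = 256
    ffn_dim: int = 1024
    order: int = 2
    max_len: int = 1024
    vocab_size: int = 28
    head_tied: bool = True

    def validate(self):
        if min(self.n_layers, self.embed_dim, self.ffn_dim, self.order,
               self.max_len, self.vocab_size) < 1:
            raise ValueError(f"invalid model config: {self}")

    def to_dict(self) -> dict:
        return asdict(self)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.lin1 = Linear(dim, hidden, rng)
        self.lin2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).gelu())


class HyenaBlock(Module):
    """Pre-norm residual block: x + Op(LN(x)); x + FFN(LN(x))."""

    def __init__(self, dim: int, ffn_dim: int, order: int,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.mixer = HyenaOperator(dim, order, rng)
        self.norm2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.mixer(self.norm1(x))
        x = x + self.ffn(self.norm2(x))
        return x


class ProtHyenaLM(Module):
    """Causal protein language model with Hyena mixing layers."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.embedding = Embedding(config.vocab_size, config.embed_dim, rng)
        self.blocks = [HyenaBlock(config.embed_dim, config.ffn_dim,
                                  config.order, rng)
                       for _ in range(config.n_layers)]
        self.norm_f = LayerNorm(config.embed_dim)
        if not config.head_tied:
            self.head = Linear(config.embed_dim, config.vocab_size, rng,
                               bias=False)

    def _check_len(self, ids: np.ndarray):
        if ids.shape[-1] > self.config.max_len:
            raise ValueError(
                f"sequence length {ids.shape[-1]} exceeds max_len "
                f"{self.config.max_len}")

    def embed(self, ids: np.ndarray) -> Tensor:
        """Final-layer representations after the last normalization, (B,L,D)."""
        ids = np.atleast_2d(np.asarray(ids))
        self._check_len(ids)
        h = self.embedding(ids)
        for block in self.blocks:
            h = block(h)
        return self.norm_f(h)

    def forward(self, ids: np.ndarray) -> Tensor:
        """Next-token logits, (B, L, vocab_size)."""
        h = self.embed(ids)
        if self.config.head_tied:
            return h @ self.embedding.weight.transpose()
        return self.head(h)

    def logits(self, ids: np.ndarray) -> np.ndarray:
        """Numpy logits for a single sequence or a batch."""
        ids = np.asarray(ids)
        single = ids.ndim == 1
        out = self.forward(ids).data
        return out[0] if single else out


def build_model(config: ModelConfig | None = None, seed: int = 0) -> ProtHyenaLM:
    """Deterministically initialized model; same seed -> identical params."""
    return ProtHyenaLM(config or ModelConfig(), seed=seed)


def count_parameters(model: Module) -> int:
    return model.count_parameters()


def params_in_millions(model: Module, decimals: int = 1) -> float:
    """Trainable parameters in millions, rounded to ``decimals``."""
    return round(model.count_parameters() / 1e6, decimals)


def extract_embeddings(tokens, model: ProtHyenaLM) -> np.ndarray:
    """Final-layer, pre-head representation of one token sequence, (L, D)."""
    ids = np.asarray(getattr(tokens, "ids", tokens))
    return model.embed(ids).data[0]
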