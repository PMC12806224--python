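"""Baseline architectures: causal self-attention decoders and a residual CNN.

The attention decoders ("ProtGPT-tiny" and "ProtGPT-base") share the
tokenizer, pre-norm block layout, tied decoding head and training loop with
the Hyena model, differing only in the sequence mixer: multi-head causal
self-attention with scaled scores and parameter-free rotary position
embeddings (a learned position table would overshoot the base model's
25.2 M parameter budget). The CNN baseline is a 35-block dilated residual
regressor used for the fitness-landscape task.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor
from .nn import Module, Linear, Embedding, LayerNorm, Parameter
from .model import FeedForward

__all__ = ["GPTConfig", "CausalSelfAttention", "ProtGPTLM", "build_protgpt",
           "CNNConfig", "CNNRegressor", "build_cnn_regressor",
           "GPT_TINY", "GPT_BASE"]


@dataclass
class GPTConfig:
    n_layers: int = 2
    embed_dim: int = 256
    ffn_dim: int = 1024
    max_len: int = 1024
    vocab_size: int = 28
    n_heads: int = 4

    def validate(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must divide evenly into heads")
        if (self.embed_dim // self.n_heads) % 2:
            raise ValueError("head dimension must be even for rotary rotation")

    def to_dict(self) -> dict:
        return asdict(self)


def GPT_TINY() -> GPTConfig:
    return GPTConfig(n_layers=2, embed_dim=256, ffn_dim=1024, max_len=1024,
                     vocab_size=28, n_heads=4)


def GPT_BASE() -> GPTConfig:
    return GPTConfig(n_layers=8, embed_dim=512, ffn_dim=2048, max_len=512,
                     vocab_size=28, n_heads=8)


def _rotary_angles(L: int, head_dim: int):
    half = head_dim // 2
    inv_freq = 10000.0 ** (-np.arange(half) / half)
    ang = np.arange(L)[:, None] * inv_freq[None, :]
    return np.cos(ang), np.sin(ang)


class CausalSelfAttention(Module):
    """Multi-head attention over positions <= t with 1/sqrt(d_head) scaling."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 rotary: bool = True):
        self.dim = dim
        self.n_heads = n_heads
        self.rotary_enabled = rotary
        self.w_q = Linear(dim, dim, rng)
        self.w_k = Linear(dim, dim, rng)
        self.w_v = Linear(dim, dim, rng)
        self.w_o = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        H = self.n_heads
        dh = D // H

        def heads(t: Tensor) -> Tensor:
            # (B, L, D) -> (B, H, L, dh)
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q, k, v = heads(self.w_q(x)), heads(self.w_k(x)), heads(self.w_v(x))
        if self.rotary_enabled:
            cos, sin = _rotary_angles(L, dh)
            q = q.rotary(cos, sin)
            k = k.rotary(cos, sin)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        mask = np.triu(np.full((L, L), -1e30), k=1)
        attn = (scores + Tensor(mask)).softmax(axis=-1)
        y = attn @ v  # (B, H, L, dh)
        y = y.transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.w_o(y)


class AttentionBlock(Module):
    def __init__(self, dim: int, ffn_dim: int, n_heads: int,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.mixer = CausalSelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.mixer(self.norm1(x))
        x = x + self.ffn(self.norm2(x))
        return x


class ProtGPTLM(Module):
    """Decoder-only attention language model with a tied head."""

    def __init__(self, config: GPTConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.embedding = Embedding(config.vocab_size, config.embed_dim, rng)
        self.blocks = [AttentionBlock(config.embed_dim, config.ffn_dim,
                                      config.n_heads, rng)
                       for _ in range(config.n_layers)]
        self.norm_f = LayerNorm(config.embed_dim)

    def embed(self, ids: np.ndarray) -> Tensor:
        ids = np.atleast_2d(np.asarray(ids))
        if ids.shape[-1] > self.config.max_len:
            raise ValueError(
                f"sequence length {ids.shape[-1]} exceeds max_len "
                f"{self.config.max_len}")
        h = self.embedding(ids)
        for block in self.blocks:
            h = block(h)
        return self.norm_f(h)

    def forward(self, ids: np.ndarray) -> Tensor:
        return self.embed(ids) @ self.embedding.weight.transpose()

    def logits(self, ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(ids)
        single = ids.ndim == 1
        out = self.forward(ids).data
        return out[0] if single else out


def build_protgpt(config: GPTConfig | None = None, seed: int = 0) -> ProtGPTLM:
    return ProtGPTLM(config or GPT_TINY(), seed=seed)


# ----------------------------------------------------------------- CNN baseline

@dataclass
class CNNConfig:
    n_blocks: int = 35
    filters: int = 256
    kernel: int = 9
    dilation: int = 2
    in_channels: int = 25   # amino-acid channels (standard + rare)

    def to_dict(self) -> dict:
        return asdict(self)


class ConvLayer(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        std = 1.0 / np.sqrt(c_in * kernel)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(kernel, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d_same(self.weight, self.bias, dilation=self.dilation)


class ResidualBlock(Module):
    """conv -> ReLU -> conv, plus identity skip, ReLU on the sum."""

    def __init__(self, filters: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        self.conv1 = ConvLayer(filters, filters, kernel, dilation, rng)
        self.conv2 = ConvLayer(filters, filters, kernel, dilation, rng)

    def forward(self, x: Tensor) -> Tensor:
        return (x + self.conv2(self.conv1(x).relu())).relu()


class CNNRegressor(Module):
    """Dilated residual CNN mapping a one-hot sequence to one scalar."""

    def __init__(self, config: CNNConfig | None = None, seed: int = 0):
        config = config or CNNConfig()
        self.config = config
        rng = np.random.default_rng(seed)
        self.stem = ConvLayer(config.in_channels, config.filters,
                              config.kernel, 1, rng)
        self.blocks = [ResidualBlock(config.filters, config.kernel,
                                     config.dilation, rng)
                       for _ in range(config.n_blocks)]
        self.head = Linear(config.filters, 1, np.random.default_rng(seed + 1))

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, L, in_channels) one-hot -> (B,) scalar predictions."""
        h = self.stem(x).relu()
        for block in self.blocks:
            h = block(h)
        pooled = h.mean(axis=1)          # global average pooling over length
        return self.head(pooled).reshape(-1)

    def predict(self, onehot: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(np.atleast_3d(onehot))).data


def build_cnn_regressor(config: CNNConfig | None = None,
                        seed: int = 0) -> CNNRegressor:
    return CNNRegressor(config, seed=seed)
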