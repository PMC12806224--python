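"""Protein vocabulary and character-level tokenization.

Each amino acid is one token. The vocabulary holds the 20 standard amino
acids in a fixed order, five extended codes for rare or ambiguous residues
(X, B, Z, U, O), and three special tokens (pad, sep, unk) — 28 tokens total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STANDARD_AMINO_ACIDS = tuple("DNEKVYAQMITLRFGCSPHW")
RARE_AMINO_ACIDS = tuple("XBZUO")
SPECIAL_TOKENS = ("<pad>", "<sep>", "<unk>")

__all__ = ["Vocabulary", "TokenSequence", "build_vocabulary", "encode", "decode",
           "STANDARD_AMINO_ACIDS", "RARE_AMINO_ACIDS", "SPECIAL_TOKENS"]


@dataclass(frozen=True)
class Vocabulary:
    standard_tokens: tuple = STANDARD_AMINO_ACIDS
    rare_tokens: tuple = RARE_AMINO_ACIDS
    special_tokens: tuple = SPECIAL_TOKENS
    token_to_id: dict = field(default_factory=dict)

    def __post_init__(self):
        tokens = list(self.standard_tokens) + list(self.rare_tokens) \
            + list(self.special_tokens)
        if len(set(tokens)) != len(tokens):
            raise ValueError("vocabulary tokens must be distinct")
        mapping = {tok: i for i, tok in enumerate(tokens)}
        object.__setattr__(self, "token_to_id", mapping)

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.token_to_id["<pad>"]

    @property
    def sep_id(self) -> int:
        return self.token_to_id["<sep>"]

    @property
    def unk_id(self) -> int:
        return self.token_to_id["<unk>"]

    @property
    def amino_acid_tokens(self) -> tuple:
        """The 25 residue characters (standard + rare)."""
        return self.standard_tokens + self.rare_tokens

    def id(self, token: str) -> int:
        return self.token_to_id[token]


@dataclass(frozen=True)
class TokenSequence:
    ids: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids",
                           np.asarray(self.ids, dtype=np.int64))
        if self.ids.ndim != 1 or self.ids.size == 0:
            raise ValueError("TokenSequence requires a nonempty 1-D id array")

    def __len__(self) -> int:
        return int(self.ids.size)


def build_vocabulary() -> Vocabulary:
    """Return the fixed 28-token vocabulary (deterministic)."""
    return Vocabulary()


def encode(sequence: str, vocab: Vocabulary | None = None,
           max_len: int | None = None, on_overflow: str = "truncate") -> TokenSequence:
    """Encode an amino-acid string, one token per character.

    Input is upper-cased first. Characters outside the 25 residue codes map to
    the unk token. Sequences longer than ``max_len`` are right-truncated
    (``on_overflow="truncate"``) or rejected (``on_overflow="error"``).
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    vocab = vocab or build_vocabulary()
    seq = sequence.upper()
    if max_len is not None and len(seq) > max_len:
        if on_overflow == "error":
            raise ValueError(
                f"sequence length {len(seq)} exceeds maximum {max_len}")
        seq = seq[:max_len]
    unk = vocab.unk_id
    ids = np.fromiter((vocab.token_to_id.get(ch, unk) for ch in seq),
                      dtype=np.int64, count=len(seq))
    return TokenSequence(ids)


def decode(tokens: TokenSequence, vocab: Vocabulary | None = None,
           special_char: str = "-") -> str:
    """Inverse of :func:`encode` on residue tokens.

    Special tokens (pad/sep/unk) render as ``special_char``... except unk,
    which has no unique preimage and also renders as ``special_char``.
    """
    vocab = vocab or build_vocabulary()
    ids = tokens.ids if isinstance(tokens, TokenSequence) else \
        TokenSequence(tokens).ids
    if ids.min() < 0 or ids.max() >= vocab.size:
        raise ValueError("token id out of range")
    residues = vocab.amino_acid_tokens
    return "".join(residues[i] if i < len(residues) else special_char
                   for i in ids)
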