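"""Seeded synthetic corpora and task datasets with analytically known truth.

Three generators cover the pipeline:

* :class:`MarkovSource` / :func:`markov_proteome` — first-order (or
  memoryless) Markov chains over the 20 standard amino acids with an exactly
  computed entropy rate H*, so e^{H*} is the optimal held-out perplexity for
  any predictor and serves as the pretraining oracle.
* :func:`motif_task` — binary classification with a degenerate
  position-weight motif implanted in positives, at protein or residue
  resolution, with configurable class imbalance (presets mirror the
  benchmark suite's ~3:7, ~2:8, balanced and near-degenerate ratios).
* :func:`landscape_task` — a mutational fitness landscape around a parent
  sequence (additive per-site effects + pairwise epistasis + Gaussian
  noise), split by mutation distance (train <= 3, test >= 4), which induces
  a label-distribution shift between the splits.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vocab import STANDARD_AMINO_ACIDS
from .tasks import TaskSpec, TaskRecord, TaskDataset

__all__ = ["MarkovSource", "entropy_rate", "markov_proteome", "MotifSpec",
           "motif_task", "LandscapeModel", "landscape_task",
           "CLASS_RATIO_PRESETS"]

ALPHABET = STANDARD_AMINO_ACIDS
N_STATES = len(ALPHABET)

#: positive-class fractions mirroring the benchmark tasks' label imbalances
CLASS_RATIO_PRESETS = {
    "neuropeptide": 0.7,     # 0:1 approximately 3:7
    "signal_peptide": 0.8,   # 0:1 about 2:8
    "solubility": 0.5,       # balanced
    "disorder": 0.99,        # near-degenerate: almost all labels are 1
}


# ------------------------------------------------------------- Markov corpora

@dataclass(frozen=True)
class MarkovSource:
    """A first-order Markov chain over the 20 standard amino acids.

    ``trans`` is the row-stochastic transition matrix; the initial state is
    drawn from the stationary distribution, so every emitted symbol after
    the first has conditional entropy equal to the chain's entropy rate.
    """
    trans: np.ndarray
    order: int = 1

    def __post_init__(self):
        trans = np.asarray(self.trans, dtype=np.float64)
        if trans.shape != (N_STATES, N_STATES):
            raise ValueError(f"transition matrix must be {N_STATES}x{N_STATES}")
        if np.any(trans < 0) or not np.allclose(trans.sum(axis=1), 1.0):
            raise ValueError("transition rows must be probability vectors")
        object.__setattr__(self, "trans", trans)

    @classmethod
    def uniform(cls) -> "MarkovSource":
        """Memoryless uniform source: every row the uniform distribution."""
        return cls(np.full((N_STATES, N_STATES), 1.0 / N_STATES), order=0)

    @classmethod
    def preferred_successor(cls, stay: float = 0.5,
                            seed: int = 0) -> "MarkovSource":
        """Each state puts mass ``stay`` on one designated successor
        (a seeded permutation) and spreads the rest uniformly."""
        rng = np.random.default_rng(seed)
        perm = rng.permutation(N_STATES)
        trans = np.full((N_STATES, N_STATES), (1.0 - stay) / (N_STATES - 1))
        trans[np.arange(N_STATES), perm] = stay
        return cls(trans)

    @classmethod
    def random(cls, seed: int = 0, concentration: float = 1.0) -> "MarkovSource":
        """Rows drawn from a symmetric Dirichlet."""
        rng = np.random.default_rng(seed)
        trans = rng.dirichlet(np.full(N_STATES, concentration), size=N_STATES)
        return cls(trans)

    def stationary(self) -> np.ndarray:
        """Stationary distribution via the leading left eigenvector."""
        vals, vecs = np.linalg.eig(self.trans.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        if abs(vals[idx] - 1.0) > 1e-8:
            raise ValueError("chain has no unit eigenvalue (not stochastic?)")
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        pi = pi / pi.sum()
        # reject reducible chains: stationary mass must reach every state
        # that the chain can occupy from it
        if np.any(pi < 1e-12):
            reach = np.linalg.matrix_power(
                (self.trans > 0).astype(float) + np.eye(N_STATES), N_STATES)
            if not np.all(reach > 0):
                raise ValueError("chain is reducible; entropy rate undefined")
        return pi


def entropy_rate(source: MarkovSource) -> float:
    """Exact H* = -sum_s pi(s) sum_t P(s,t) log P(s,t), in nats/symbol."""
    pi = source.stationary()
    P = source.trans
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(-(pi * plogp.sum(axis=1)).sum())


def markov_proteome(source: MarkovSource, n: int,
                    length_range: tuple = (50, 300),
                    seed: int = 0) -> tuple:
    """Sample ``n`` sequences from the chain; returns (records, H*).

    ``records`` is a list of (id, sequence) pairs ready for FASTA output.
    """
    if n < 1:
        raise ValueError("need n >= 1 sequences")
    rng = np.random.default_rng(seed)
    pi = source.stationary()
    cum_trans = np.cumsum(source.trans, axis=1)
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    records = []
    for i, L in enumerate(lengths):
        states = np.empty(L, dtype=np.int64)
        states[0] = rng.choice(N_STATES, p=pi)
        u = rng.random(L - 1)
        for t in range(1, L):
            states[t] = np.searchsorted(cum_trans[states[t - 1]], u[t - 1])
        seq = "".join(ALPHABET[s] for s in states)
        records.append((f"synth_{i}", seq))
    return records, entropy_rate(source)


# ----------------------------------------------------------------- motif tasks

@dataclass(frozen=True)
class MotifSpec:
    """A degenerate motif: at each position a small allowed residue set."""
    allowed: tuple  # tuple of strings, one per motif position

    @classmethod
    def default(cls, length: int = 8, choices_per_site: int = 2,
                seed: int = 0) -> "MotifSpec":
        rng = np.random.default_rng(seed)
        allowed = tuple(
            "".join(ALPHABET[j] for j in
                    rng.choice(N_STATES, size=choices_per_site, replace=False))
            for _ in range(length))
        return cls(allowed)

    def __len__(self) -> int:
        return len(self.allowed)

    def sample(self, rng: np.random.Generator) -> str:
        return "".join(site[rng.integers(len(site))] for site in self.allowed)


def _background(rng: np.random.Generator, L: int) -> list:
    return [ALPHABET[i] for i in rng.integers(N_STATES, size=L)]


def motif_task(n: int, motif: MotifSpec | None = None,
               class_ratio: float = 0.7, resolution: str = "protein",
               length_range: tuple = (40, 80), seed: int = 0,
               test_fraction: float = 0.2) -> TaskDataset:
    """Binary task: positives carry one implanted motif, negatives none.

    ``class_ratio`` is the positive-class fraction (presets in
    :data:`CLASS_RATIO_PRESETS`). Protein resolution labels the sequence;
    residue resolution labels each position 1 inside the motif, else 0.
    The realized class ratio is exact up to rounding of n * ratio.
    """
    if not 0.0 < class_ratio < 1.0:
        raise ValueError("class_ratio must be in (0, 1)")
    n_pos = int(round(n * class_ratio))
    if n_pos == 0 or n_pos == n:
        raise ValueError(f"ratio {class_ratio} unrealizable with n={n}")
    motif = motif or MotifSpec.default(seed=seed)
    rng = np.random.default_rng(seed)
    m = len(motif)
    lo, hi = length_range
    if lo <= m:
        raise ValueError("sequences must be longer than the motif")
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    records = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        chars = _background(rng, L)
        residue_label = ["0"] * L
        if labels[i] == 1:
            start = int(rng.integers(0, L - m + 1))
            chars[start:start + m] = list(motif.sample(rng))
            residue_label[start:start + m] = ["1"] * m
        split = "test" if rng.random() < test_fraction else "train"
        label = "".join(residue_label) if resolution == "residue" \
            else int(labels[i])
        records.append(TaskRecord("".join(chars), label, split))
    spec = TaskSpec("binary", resolution=resolution, n_classes=2)
    ds = TaskDataset(spec, records,
                     ground_truth={"motif": list(motif.allowed),
                                   "class_ratio": class_ratio,
                                   "n_positive": int(n_pos)})
    return ds.validate()


# ---------------------------------------------------------- fitness landscapes

@dataclass
class LandscapeModel:
    """Additive + pairwise-epistatic fitness landscape around a parent.

    label(variant) = baseline + sum additive[site, aa] over mutated sites
                   + sum epistasis over mutated site-pairs + N(0, noise).
    Additive effects are mostly deleterious (negative mean), so accumulating
    mutations shifts labels downward — the train (distance <= 3) and test
    (distance >= 4) splits then differ in location, a distribution shift.
    """
    parent: str
    baseline: float = 3.8
    additive: np.ndarray = field(default=None)
    pair_sites: np.ndarray = field(default=None)
    pair_effects: np.ndarray = field(default=None)
    noise: float = 0.1

    @classmethod
    def default(cls, parent_length: int = 60, seed: int = 0,
                n_pairs: int = 10, effect_mean: float = -0.35,
                effect_sd: float = 0.25, epistasis_sd: float = 0.3,
                noise: float = 0.1) -> "LandscapeModel":
        rng = np.random.default_rng(seed)
        parent = "".join(ALPHABET[i]
                         for i in rng.integers(N_STATES, size=parent_length))
        additive = rng.normal(effect_mean, effect_sd,
                              size=(parent_length, N_STATES))
        # the parent residue at each site has, by definition, zero effect
        for s, ch in enumerate(parent):
            additive[s, ALPHABET.index(ch)] = 0.0
        pair_sites = np.array([
            rng.choice(parent_length, size=2, replace=False)
            for _ in range(n_pairs)])
        pair_effects = rng.normal(0.0, epistasis_sd, size=n_pairs)
        return cls(parent=parent, additive=additive, pair_sites=pair_sites,
                   pair_effects=pair_effects, noise=noise)

    def label(self, variant: str, rng: np.random.Generator | None = None) -> float:
        if len(variant) != len(self.parent):
            raise ValueError("variant length must match parent")
        mutated = {s for s, (a, b) in enumerate(zip(variant, self.parent))
                   if a != b}
        val = self.baseline
        for s in mutated:
            val += self.additive[s, ALPHABET.index(variant[s])]
        for (i, j), eff in zip(self.pair_sites, self.pair_effects):
            if i in mutated and j in mutated:
                val += eff
        if rng is not None and self.noise > 0:
            val += rng.normal(0.0, self.noise)
        return float(val)


def _mutate(parent: str, distance: int, rng: np.random.Generator) -> str:
    sites = rng.choice(len(parent), size=distance, replace=False)
    chars = list(parent)
    for s in sites:
        current = chars[s]
        choices = [c for c in ALPHABET if c != current]
        chars[s] = choices[rng.integers(len(choices))]
    return "".join(chars)


def landscape_task(model: LandscapeModel | None = None,
                   n_train: int = 2000, n_test: int = 500,
                   train_distances: tuple = (1, 3),
                   test_distances: tuple = (4, 15),
                   seed: int = 0) -> TaskDataset:
    """Regression dataset split by Hamming distance from the parent."""
    model = model or LandscapeModel.default(seed=seed)
    if len(model.parent) < 20:
        raise ValueError("parent sequence must be at least 20 residues")
    rng = np.random.default_rng(seed + 1)
    records = []
    for n, (dlo, dhi), split in ((n_train, train_distances, "train"),
                                 (n_test, test_distances, "test")):
        for _ in range(n):
            d = int(rng.integers(dlo, dhi + 1))
            variant = _mutate(model.parent, d, rng)
            records.append(TaskRecord(variant, model.label(variant, rng), split))
    spec = TaskSpec("regression", resolution="protein", n_classes=1)
    train_labels = [r.label for r in records if r.split == "train"]
    test_labels = [r.label for r in records if r.split == "test"]
    ds = TaskDataset(spec, records, ground_truth={
        "parent": model.parent,
        "baseline": model.baseline,
        "noise": model.noise,
        "train_label_mean": float(np.mean(train_labels)),
        "test_label_mean": float(np.mean(test_labels)),
    })
    return ds.validate()
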