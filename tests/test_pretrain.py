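"""Objective, schedule and training-loop behavior."""

import numpy as np
import pytest

from prothyena.model import ModelConfig, build_model
from prothyena.pretrain import (CosineSchedule, cosine_lr, nll_loss,
                                PerplexityReport, perplexity, pretrain,
                                desk_scale_config, encode_corpus)
from prothyena.synthetic import MarkovSource, markov_proteome
from prothyena.vocab import build_vocabulary


class UniformModel:
    """Assigns equal probability to a fixed subset of the vocabulary."""

    def __init__(self, support=20, vocab=28):
        self.support = support
        self.vocab = vocab

    def forward(self, ids):
        ids = np.atleast_2d(ids)
        logits = np.full((*ids.shape, self.vocab), -1e9)
        logits[..., : self.support] = 0.0

        class _Out:
            data = logits
        return _Out()


class OracleModel:
    """Puts probability ~1 on the true next token (teacher forcing)."""

    def forward(self, ids):
        ids = np.atleast_2d(ids)
        B, L = ids.shape
        logits = np.zeros((B, L, 28))
        for b in range(B):
            for t in range(L - 1):
                logits[b, t, ids[b, t + 1]] = 30.0
        return type("O", (), {"data": logits})()


class TestNLL:
    def test_perfect_prediction_zero_loss(self):
        tokens = np.array([3, 1, 4])
        logits = np.full((3, 28), -100.0)
        logits[0, 1] = 100.0   # predicts token 2
        logits[1, 4] = 100.0   # predicts token 3
        assert nll_loss(logits, tokens) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_over_20_gives_ln20(self):
        tokens = np.array([0, 5, 19, 3])
        logits = np.full((4, 28), -1e9)
        logits[:, :20] = 0.0
        assert nll_loss(logits, tokens) == pytest.approx(np.log(20.0),
                                                         abs=1e-9)

    def test_hand_computed_three_token_case(self):
        """P(a2|a1)=0.5, P(a3|a1a2)=0.25 -> (0.6931+1.3863)/2."""
        tokens = np.array([0, 1, 2])
        logits = np.full((3, 28), -np.inf)
        logits[0, [1, 2]] = np.log([0.5, 0.5])
        logits[1, [2, 3, 4, 5]] = np.log(0.25)
        loss = nll_loss(logits, tokens)
        assert loss == pytest.approx((np.log(2) + np.log(4)) / 2, abs=1e-9)

    def test_all_pad_rejected(self):
        vocab = build_vocabulary()
        tokens = np.full(4, vocab.pad_id)
        with pytest.raises(ValueError):
            nll_loss(np.zeros((4, 28)), tokens, pad_id=vocab.pad_id)


class TestPerplexity:
    def test_perfect_predictor_ppl_one(self, rng):
        corpus = [rng.integers(0, 28, size=20) for _ in range(5)]
        rep = perplexity(OracleModel(), corpus)
        assert rep.ppl == pytest.approx(1.0, abs=1e-6)

    def test_uniform_over_20_ppl_twenty(self, rng):
        corpus = [rng.integers(0, 20, size=30) for _ in range(4)]
        rep = perplexity(UniformModel(support=20), corpus)
        assert rep.ppl == pytest.approx(20.0, rel=1e-9)

    def test_identity_ppl_exp_h(self, rng):
        m = build_model(ModelConfig(n_layers=1, embed_dim=8, ffn_dim=16,
                                    max_len=64), seed=0)
        corpus = [rng.integers(0, 28, size=24) for _ in range(3)]
        rep = perplexity(m, corpus)
        assert rep.ppl == pytest.approx(np.exp(rep.H), rel=1e-9)
        assert rep.ppl >= 1.0

    def test_report_invariant_enforced(self):
        with pytest.raises(ValueError):
            PerplexityReport(H=1.0, ppl=5.0, n_positions=10)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            perplexity(UniformModel(), [])


class TestCosineSchedule:
    def test_endpoints_and_midpoint(self):
        sch = CosineSchedule(initial_lr=0.0006, min_lr=0.0,
                             total_steps=1000, warmup_steps=0)
        assert cosine_lr(0, sch) == pytest.approx(0.0006)
        assert cosine_lr(1000, sch) == pytest.approx(0.0, abs=1e-12)
        assert cosine_lr(500, sch) == pytest.approx(0.0003)

    def test_warmup_ramps_linearly(self):
        sch = CosineSchedule(initial_lr=0.001, total_steps=100,
                             warmup_steps=10)
        assert cosine_lr(4, sch) == pytest.approx(0.0005)
        assert cosine_lr(10, sch) == pytest.approx(0.001)

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(-1, CosineSchedule())


class TestTrainingLoop:
    def tiny(self, seed=0):
        return build_model(ModelConfig(n_layers=1, embed_dim=16, ffn_dim=32,
                                       max_len=64), seed=seed)

    def corpus(self, n=16, seed=1):
        recs, _ = markov_proteome(MarkovSource.uniform(), n, (20, 40),
                                  seed=seed)
        return [s for _, s in recs]

    def test_initial_loss_near_ln_vocab(self):
        """Fresh init is near-uniform over the 28 tokens."""
        seqs = self.corpus()
        cfg = desk_scale_config(total_steps=1, batch_size=8, seed=0)
        _, log = pretrain(self.tiny(), seqs, cfg, val_sequences=seqs[:2])
        assert log[0]["loss"] == pytest.approx(np.log(28.0), rel=0.10)

    def test_seeded_reproducibility(self):
        seqs = self.corpus()
        cfg = desk_scale_config(total_steps=5, batch_size=8, seed=3)
        _, log_a = pretrain(self.tiny(seed=2), seqs, cfg,
                            val_sequences=seqs[:2])
        _, log_b = pretrain(self.tiny(seed=2), seqs, cfg,
                            val_sequences=seqs[:2])
        assert [e["loss"] for e in log_a] == [e["loss"] for e in log_b]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            pretrain(self.tiny(), [], desk_scale_config(total_steps=1))

    def test_memorization_of_small_corpus(self):
        """16 fixed sequences, tiny model, 500 steps: training PPL < 1.2."""
        seqs = self.corpus(n=16, seed=4)
        model = build_model(ModelConfig(n_layers=2, embed_dim=32, ffn_dim=64,
                                        max_len=64), seed=0)
        cfg = desk_scale_config(total_steps=500, batch_size=16, lr=0.003,
                                seed=0, log_every=500)
        model, _ = pretrain(model, seqs, cfg, val_sequences=seqs[:2])
        rep = perplexity(model, encode_corpus(seqs))
        assert rep.ppl < 1.2
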