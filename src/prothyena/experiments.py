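"""Reference experiments at desk scale, shared by the benchmark script
and the acceptance test-suite.

Each function runs one self-contained, seeded experiment — generating its
synthetic inputs, training where needed, and measuring the result — and
returns a flat dict of named quantities. Problem sizes are chosen so the
full battery runs on one CPU core in minutes; docs/methods.md records the
sizes and why they are sufficient for the properties being measured.
"""

from __future__ import annotations

import numpy as np

from .model import ModelConfig, build_model, params_in_millions
from .baselines import GPTConfig, GPT_TINY, GPT_BASE, build_protgpt, \
    build_cnn_regressor
from .hyena import toeplitz_conv_reference, causal_fft_conv
from .metrics import ConfusionCounts, mcc
from .pretrain import desk_scale_config, pretrain, perplexity, encode_corpus
from .synthetic import MarkovSource, markov_proteome, entropy_rate, \
    motif_task, landscape_task
from .finetune import FinetuneConfig, attach_head, finetune

__all__ = ["parameter_counts", "analytic_perplexity", "analytic_mcc",
           "operator_exactness", "model_causality", "entropy_rate_recovery",
           "architecture_comparison", "finetuning_suite"]


def parameter_counts() -> dict:
    """Trainable-parameter totals of the four reference configurations,
    in millions at their reference rounding."""
    return {
        "prothyena_params_M": params_in_millions(build_model(ModelConfig())),
        "protgpt_tiny_params_M": params_in_millions(
            build_protgpt(GPT_TINY())),
        "protgpt_base_params_M": params_in_millions(
            build_protgpt(GPT_BASE())),
        "cnn_params_M": float(round(
            build_cnn_regressor().count_parameters() / 1e6)),
    }


def analytic_perplexity(seed: int = 0) -> dict:
    """Perplexity of two analytically known predictors on random corpora."""
    rng = np.random.default_rng(seed)
    corpus = [rng.integers(0, 20, size=50) for _ in range(20)]

    class Uniform20:
        def forward(self, ids):
            ids = np.atleast_2d(ids)
            logits = np.full((*ids.shape, 28), -1e9)
            logits[..., :20] = 0.0
            return type("O", (), {"data": logits})()

    class Oracle:
        def forward(self, ids):
            ids = np.atleast_2d(ids)
            logits = np.zeros((*ids.shape, 28))
            for b in range(ids.shape[0]):
                for t in range(ids.shape[1] - 1):
                    logits[b, t, ids[b, t + 1]] = 40.0
            return type("O", (), {"data": logits})()

    return {
        "uniform20_perplexity": perplexity(Uniform20(), corpus).ppl,
        "perfect_predictor_perplexity": perplexity(Oracle(), corpus).ppl,
    }


def analytic_mcc() -> dict:
    """MCC of the perfect, inverted and a hand-computed mixed confusion."""
    return {
        "mcc_perfect": mcc(ConfusionCounts(tp=50, tn=50, fp=0, fn=0)),
        "mcc_inverted": mcc(ConfusionCounts(tp=0, tn=0, fp=50, fn=50)),
        "mcc_mixed": mcc(ConfusionCounts(tp=90, fp=10, tn=80, fn=20)),
    }


def operator_exactness(seed: int = 0) -> dict:
    """Worst relative deviation of the FFT convolution from the O(L^2)
    Toeplitz oracle over L in {4, 16, 128, 1024}."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for L in (4, 16, 128, 1024):
        h = rng.normal(size=(L, 3))
        v = rng.normal(size=(L, 3))
        ref = toeplitz_conv_reference(h, v)
        err = np.abs(causal_fft_conv(h, v) - ref).max() / np.abs(ref).max()
        worst = max(worst, float(err))
    return {"fft_vs_toeplitz_max_rel_err": worst}


def model_causality(seed: int = 0, L: int = 32) -> dict:
    """Largest change in past logits caused by perturbing future tokens."""
    rng = np.random.default_rng(seed)
    m = build_model(ModelConfig(n_layers=2, embed_dim=16, ffn_dim=32,
                                max_len=L), seed=seed)
    ids = rng.integers(0, 28, size=L)
    base = m.logits(ids)
    leak = 0.0
    for t in range(L - 1):
        pert = ids.copy()
        pert[t + 1] = (pert[t + 1] + 1 + rng.integers(26)) % 28
        out = m.logits(pert)
        leak = max(leak, float(np.abs(out[: t + 1] - base[: t + 1]).max()))
    return {"causality_max_leak": leak}


# ---------------------------------------------------------- training batteries

def _markov_data(seed: int, n_train: int = 5000, n_held: int = 300):
    src = MarkovSource.preferred_successor(stay=0.5, seed=0)
    h_star = entropy_rate(src)
    train, _ = markov_proteome(src, n_train, (60, 100), seed=seed + 2)
    held, _ = markov_proteome(src, n_held, (60, 100), seed=seed + 3)
    return [s for _, s in train], [s for _, s in held], h_star


def entropy_rate_recovery(seed: int = 0) -> dict:
    """Pretrain a small model (D=64) on a first-order Markov corpus and
    compare held-out perplexity against the entropy-rate bound e^{H*}."""
    train, held, h_star = _markov_data(seed)
    model = build_model(ModelConfig(n_layers=2, embed_dim=64, ffn_dim=128,
                                    max_len=128), seed=seed)
    cfg = desk_scale_config(total_steps=500, batch_size=32, lr=0.003,
                            seed=seed, log_every=250)
    model, _ = pretrain(model, train, cfg, val_sequences=held)
    ppl = perplexity(model, encode_corpus(held)).ppl
    optimal = float(np.exp(h_star))
    return {
        "markov_entropy_rate_nats": h_star,
        "markov_optimal_ppl": optimal,
        "markov_heldout_ppl": ppl,
        "markov_ppl_over_optimal": ppl / optimal,
    }


def architecture_comparison(seed: int = 0) -> dict:
    """Hyena vs attention at a matched ~50k-parameter budget on identical
    data, steps and seed policy; reports both held-out perplexities."""
    train, held, h_star = _markov_data(seed)
    hyena = build_model(ModelConfig(n_layers=2, embed_dim=48, ffn_dim=96,
                                    max_len=128), seed=seed + 1)
    attn = build_protgpt(GPTConfig(n_layers=2, embed_dim=48, ffn_dim=160,
                                   max_len=128, n_heads=4), seed=seed + 1)
    cfg = desk_scale_config(total_steps=400, batch_size=32, lr=0.003,
                            seed=seed + 7, log_every=400)
    hyena, _ = pretrain(hyena, train, cfg, val_sequences=held)
    attn, _ = pretrain(attn, train, cfg, val_sequences=held)
    held_ids = encode_corpus(held)
    h_ppl = perplexity(hyena, held_ids).ppl
    a_ppl = perplexity(attn, held_ids).ppl
    return {
        "hyena_budget_params": hyena.count_parameters(),
        "attention_budget_params": attn.count_parameters(),
        "hyena_heldout_ppl": h_ppl,
        "attention_heldout_ppl": a_ppl,
        "hyena_over_attention_ppl": h_ppl / a_ppl,
    }


def finetuning_suite(seed: int = 0) -> dict:
    """Three downstream tasks on synthetic data with known structure:
    protein-level motif classification (3:7 imbalance), residue-level
    motif tagging, and distance-split epistatic landscape regression."""
    out = {}

    ds = motif_task(2500, class_ratio=0.7, resolution="protein",
                    seed=seed + 8)
    bb = build_model(ModelConfig(n_layers=2, embed_dim=32, ffn_dim=64,
                                 max_len=128), seed=seed + 2)
    _, rep = finetune(attach_head(bb, ds.spec, seed=seed + 2), ds,
                      FinetuneConfig(epochs=12, lr=1e-3, batch_size=32,
                                     seed=seed + 2))
    out["motif_protein_auroc"] = rep["auroc"]
    out["motif_protein_mcc"] = rep["mcc"]

    dsr = motif_task(1200, class_ratio=0.7, resolution="residue",
                     seed=seed + 9)
    bbr = build_model(ModelConfig(n_layers=2, embed_dim=32, ffn_dim=64,
                                  max_len=128), seed=seed + 3)
    _, rep = finetune(attach_head(bbr, dsr.spec, seed=seed + 3), dsr,
                      FinetuneConfig(epochs=6, lr=3e-3, batch_size=32,
                                     seed=seed + 3))
    out["motif_residue_mcc"] = rep["mcc"]
    out["motif_residue_accuracy"] = rep["accuracy"]

    # out-of-distribution split: early stopping on in-distribution validation
    # loss is uninformative here, so the full cosine schedule is run
    dsl = landscape_task(n_train=2000, n_test=500, seed=seed + 10)
    bbl = build_model(ModelConfig(n_layers=2, embed_dim=32, ffn_dim=64,
                                  max_len=64), seed=seed + 4)
    _, rep = finetune(attach_head(bbl, dsl.spec, seed=seed + 4), dsl,
                      FinetuneConfig(epochs=30, lr=1e-3, batch_size=32,
                                     seed=seed + 4,
                                     early_stop_patience=10 ** 6))
    out["landscape_test_spearman"] = rep["spearman"]
    out["landscape_test_mse"] = rep["mse"]
    return out
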