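"""Synthetic generators: entropy rates, class ratios, landscape structure."""

import numpy as np
import pytest

from prothyena.synthetic import (MarkovSource, entropy_rate, markov_proteome,
                                 MotifSpec, motif_task, LandscapeModel,
                                 landscape_task, CLASS_RATIO_PRESETS, ALPHABET)


class TestEntropyRate:
    def test_uniform_memoryless(self):
        assert entropy_rate(MarkovSource.uniform()) == pytest.approx(
            np.log(20.0), abs=1e-12)

    def test_two_state_skeleton_formula(self):
        """A stay-probability-0.9 two-choice structure has the binary-entropy
        rate -(0.9 ln 0.9 + 0.1 ln 0.1) on its 2-state skeleton."""
        p = 0.9
        trans = np.zeros((20, 20))
        for s in range(20):
            trans[s, s] = p
            trans[s, (s + 1) % 20] = 1 - p
        h = entropy_rate(MarkovSource(trans))
        expected = -(p * np.log(p) + (1 - p) * np.log(1 - p))
        assert h == pytest.approx(expected, abs=1e-10)

    def test_deterministic_cycle_zero_entropy(self):
        trans = np.zeros((20, 20))
        for s in range(20):
            trans[s, (s + 1) % 20] = 1.0
        assert entropy_rate(MarkovSource(trans)) == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_matches_empirical_nll(self):
        """Exact H* agrees with a long-run empirical NLL estimate."""
        src = MarkovSource.random(seed=4, concentration=2.0)
        h = entropy_rate(src)
        recs, _ = markov_proteome(src, 60, (400, 500), seed=5)
        idx = {c: i for i, c in enumerate(ALPHABET)}
        nll, n = 0.0, 0
        for _, seq in recs:
            states = [idx[c] for c in seq]
            for a, b in zip(states[:-1], states[1:]):
                nll -= np.log(src.trans[a, b])
                n += 1
        assert nll / n == pytest.approx(h, rel=0.01)

    def test_invalid_transitions_rejected(self):
        with pytest.raises(ValueError):
            MarkovSource(np.ones((20, 20)))


class TestMarkovProteome:
    def test_deterministic_given_seed(self):
        src = MarkovSource.preferred_successor(seed=1)
        a, _ = markov_proteome(src, 10, (20, 40), seed=3)
        b, _ = markov_proteome(src, 10, (20, 40), seed=3)
        assert a == b
        c, _ = markov_proteome(src, 10, (20, 40), seed=4)
        assert a != c

    def test_lengths_and_alphabet(self):
        src = MarkovSource.uniform()
        recs, h = markov_proteome(src, 25, (30, 50), seed=0)
        assert len(recs) == 25
        assert h == pytest.approx(np.log(20.0))
        for _, seq in recs:
            assert 30 <= len(seq) <= 50
            assert set(seq) <= set(ALPHABET)


class TestMotifTask:
    def test_exact_class_ratio(self):
        ds = motif_task(1000, class_ratio=0.7, seed=0)
        pos = sum(r.label for r in ds.records)
        assert pos == 700  # 3:7 preset, exact up to rounding

    def test_presets_cover_benchmark_imbalances(self):
        assert CLASS_RATIO_PRESETS["neuropeptide"] == 0.7
        assert CLASS_RATIO_PRESETS["signal_peptide"] == 0.8
        assert CLASS_RATIO_PRESETS["solubility"] == 0.5
        assert CLASS_RATIO_PRESETS["disorder"] >= 0.99

    def test_near_degenerate_preset_generates(self):
        ds = motif_task(500, class_ratio=CLASS_RATIO_PRESETS["disorder"],
                        seed=0)
        pos = sum(r.label for r in ds.records)
        assert pos == round(500 * 0.99)

    def test_positives_contain_motif_negatives_do_not(self):
        motif = MotifSpec.default(seed=3)
        ds = motif_task(300, motif=motif, class_ratio=0.5, seed=3)
        sites = motif.allowed

        def contains(seq):
            m = len(sites)
            return any(all(seq[s + k] in sites[k] for k in range(m))
                       for s in range(len(seq) - m + 1))

        for rec in ds.records:
            if rec.label == 1:
                assert contains(rec.sequence)
        false_pos = sum(contains(r.sequence) for r in ds.records
                        if r.label == 0)
        assert false_pos / 150 < 0.1  # chance matches are rare

    def test_residue_labels_align_with_sequence(self):
        ds = motif_task(100, class_ratio=0.5, resolution="residue", seed=1)
        for rec in ds.records:
            assert len(rec.label) == len(rec.sequence)
            assert set(rec.label) <= {"0", "1"}

    def test_impossible_ratio_rejected(self):
        with pytest.raises(ValueError):
            motif_task(10, class_ratio=0.999, seed=0)


class TestLandscape:
    def test_parent_maps_to_baseline(self):
        model = LandscapeModel.default(seed=0)
        assert model.label(model.parent) == pytest.approx(model.baseline)

    def test_additive_limit_recovered_by_linear_regression(self):
        """Without epistasis and noise, labels are exactly linear in one-hot
        mutation indicators."""
        model = LandscapeModel.default(seed=1, n_pairs=0, noise=0.0)
        ds = landscape_task(model, n_train=300, n_test=50, seed=1)
        P, A = len(model.parent), 20
        X = np.zeros((len(ds.records), P * A))
        y = np.empty(len(ds.records))
        for i, rec in enumerate(ds.records):
            for s, (a, b) in enumerate(zip(rec.sequence, model.parent)):
                if a != b:
                    X[i, s * A + ALPHABET.index(a)] = 1.0
            y[i] = rec.label
        coef, *_ = np.linalg.lstsq(
            np.hstack([X, np.ones((len(y), 1))]), y, rcond=None)
        resid = np.hstack([X, np.ones((len(y), 1))]) @ coef - y
        assert np.abs(resid).max() < 1e-8

    def test_distance_split_and_label_shift(self):
        ds = landscape_task(n_train=800, n_test=400, seed=2)
        parent = ds.ground_truth["parent"]

        def dist(seq):
            return sum(a != b for a, b in zip(seq, parent))

        train = ds.split("train")
        test = ds.split("test")
        assert all(1 <= dist(r.sequence) <= 3 for r in train)
        assert all(4 <= dist(r.sequence) <= 15 for r in test)
        # mostly-deleterious effects shift the test labels downward
        shift = np.mean([r.label for r in train]) - \
            np.mean([r.label for r in test])
        assert shift > 0.5

    def test_bit_reproducible(self):
        a = landscape_task(n_train=50, n_test=20, seed=9)
        b = landscape_task(n_train=50, n_test=20, seed=9)
        assert [(r.sequence, r.label) for r in a.records] == \
            [(r.sequence, r.label) for r in b.records]
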