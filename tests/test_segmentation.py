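import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioword.segmentation import (
    SegmentationError,
    Vocabulary,
    WordLoss,
    corpus_log_likelihood,
    em_estimate,
    em_likelihood_trajectory,
    kmer_tokenize,
    learn_vocabulary,
    prune_vocabulary,
    seed_vocabulary,
    viterbi_segment,
    word_losses,
)
from tests.conftest import brute_force_best_log_prob, brute_force_marginal


class TestVocabularyInvariants:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(SegmentationError, match="sum"):
            Vocabulary({"A": 0.5, "B": 0.4})

    def test_non_positive_probability_rejected(self):
        with pytest.raises(SegmentationError):
            Vocabulary({"A": 1.0, "B": 0.0})


class TestSeedVocabulary:
    def test_most_frequent_pair_merged(self):
        vocab = seed_vocabulary(["ABAB", "ABAB"], 3)
        assert set(vocab.entries) == {"A", "B", "AB"}

    def test_single_residue_corpus(self):
        vocab = seed_vocabulary(["A"], 1)
        assert vocab.entries == {"A": 1.0}

    def test_tie_broken_toward_smallest_pair(self):
        # (A,C), (C,D), (D,C) all occur twice; lexicographic tie-break picks AC
        vocab = seed_vocabulary(["ACDC", "ACDC"], 5)
        assert {"A", "C", "D", "AC"} <= set(vocab.entries)

    def test_seed_size_below_alphabet_rejected(self):
        with pytest.raises(SegmentationError, match="alphabet"):
            seed_vocabulary(["ABC"], 2)

    def test_probabilities_sum_to_one(self):
        vocab = seed_vocabulary(["MKVMKV", "MKAMKA"], 8)
        assert math.isclose(sum(vocab.entries.values()), 1.0, abs_tol=1e-9)


class TestEM:
    def test_singleton_vocab_converges_to_residue_frequencies(self):
        # with only one segmentation per sentence, EM is closed-form counting
        vocab = Vocabulary({"A": 0.5, "B": 0.5})
        out = em_estimate(["AAB", "AB"], vocab, max_iterations=3)
        assert out.entries["A"] == pytest.approx(0.6, abs=1e-6)
        assert out.entries["B"] == pytest.approx(0.4, abs=1e-6)

    def test_likelihood_non_decreasing(self):
        vocab = Vocabulary({"A": 0.3, "B": 0.3, "AB": 0.4})
        traj = em_likelihood_trajectory(["AB", "AAB", "ABAB"], vocab, 10)
        assert all(b >= a - 1e-9 for a, b in zip(traj, traj[1:]))

    def test_infinite_tolerance_returns_after_one_iteration(self):
        vocab = Vocabulary({"A": 0.3, "B": 0.3, "AB": 0.4})
        out = em_estimate(["ABAB"], vocab, max_iterations=50,
                          tolerance=math.inf)
        assert math.isclose(sum(out.entries.values()), 1.0, abs_tol=1e-9)
        one_step = em_estimate(["ABAB"], vocab, max_iterations=1)
        assert out.entries == one_step.entries

    def test_uncovered_sentence_names_the_sentence(self):
        vocab = Vocabulary({"A": 1.0})
        with pytest.raises(SegmentationError, match="AXB"):
            em_estimate(["AXB"], vocab)

    def test_marginal_likelihood_matches_enumeration(self):
        entries = {"A": 0.25, "B": 0.25, "AB": 0.3, "BA": 0.2}
        vocab = Vocabulary(entries)
        corpus = ["ABAB", "BABA", "AABB"]
        expected = sum(brute_force_marginal(s, entries) for s in corpus)
        assert corpus_log_likelihood(corpus, vocab) == pytest.approx(expected)


class TestViterbi:
    def test_singletons_only_single_candidate(self, singleton_vocab):
        seg = viterbi_segment("ACB", singleton_vocab)
        assert seg.tokens == ("A", "C", "B")

    def test_prefers_higher_probability_word(self, mixed_vocab):
        seg = viterbi_segment("AB", mixed_vocab)
        assert seg.tokens == ("AB",)
        assert seg.log_probability == pytest.approx(math.log(0.5))

    def test_tokens_reconstruct_input(self, mixed_vocab):
        seg = viterbi_segment("ABAAB", mixed_vocab)
        assert "".join(seg.tokens) == "ABAAB"

    def test_log_probability_is_sum_of_token_logs(self, mixed_vocab):
        seg = viterbi_segment("ABA", mixed_vocab)
        expected = sum(math.log(mixed_vocab.entries[t]) for t in seg.tokens)
        assert seg.log_probability == pytest.approx(expected)

    def test_unsegmentable_sequence_fails(self, mixed_vocab):
        with pytest.raises(SegmentationError, match="not segmentable"):
            viterbi_segment("AXB", mixed_vocab)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_enumeration(self, data):
        rng_words = ["A", "B", "C", "AB", "BC", "ABC", "BA", "CB", "AA"]
        chosen = data.draw(st.sets(st.sampled_from(rng_words), min_size=1))
        chosen |= {"A", "B", "C"}  # keep every string coverable
        raw = {w: data.draw(st.floats(0.05, 1.0)) for w in chosen}
        total = sum(raw.values())
        vocab = Vocabulary({w: p / total for w, p in raw.items()})
        seq = data.draw(st.text(alphabet="ABC", min_size=1, max_size=10))
        seg = viterbi_segment(seq, vocab)
        oracle = brute_force_best_log_prob(seq, vocab.entries)
        assert seg.log_probability == pytest.approx(oracle, abs=1e-9)
        assert "".join(seg.tokens) == seq


class TestWordLosses:
    def test_absent_word_has_zero_loss(self):
        vocab = Vocabulary({"A": 0.4, "B": 0.3, "CD": 0.3})
        losses = {wl.word: wl.loss for wl in word_losses(["AB"], vocab)}
        assert losses["CD"] == 0.0

    def test_contributing_word_has_positive_loss(self):
        entries = {"A": 0.3, "B": 0.3, "AB": 0.4}
        vocab = Vocabulary(entries)
        losses = {wl.word: wl.loss for wl in word_losses(["AB"], vocab)}
        # enumeration: F with AB = log(pA*pB + pAB); without = log(pA*pB)
        expected = math.log(0.3 * 0.3 + 0.4) - math.log(0.3 * 0.3)
        assert losses["AB"] == pytest.approx(expected)
        assert losses["AB"] > 0

    def test_singletons_are_never_removable(self):
        vocab = Vocabulary({"A": 0.5, "B": 0.5})
        assert all(wl.loss == math.inf for wl in word_losses(["AB"], vocab))


class TestPruning:
    def _uniform_vocab(self, n_multi):
        # distinct multi-residue words, built deterministically
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        words = set()
        i = 0
        while len(words) < n_multi:
            words.add(alphabet[i % 20] + alphabet[(i // 20) % 20] + alphabet[i % 7])
            i += 1
        entries = {w: 1.0 for w in words}
        entries.update({c: 1.0 for c in "ACD"})
        total = sum(entries.values())
        return Vocabulary({w: p / total for w, p in entries.items()})

    def test_alpha_70_keeps_exactly_70_of_100(self):
        vocab = self._uniform_vocab(100)
        losses = [WordLoss(w, float(i)) for i, w in enumerate(sorted(vocab.entries))
                  if len(w) > 1]
        losses += [WordLoss(w, math.inf) for w in vocab.entries if len(w) == 1]
        pruned = prune_vocabulary(vocab, losses, 70)
        assert sum(1 for w in pruned.entries if len(w) > 1) == 70

    def test_alpha_100_keeps_everything(self):
        vocab = self._uniform_vocab(10)
        losses = word_losses(["ACD"], vocab)
        pruned = prune_vocabulary(vocab, losses, 100)
        assert set(pruned.entries) == set(vocab.entries)

    def test_highest_loss_words_retained(self):
        entries = {c: 0.1 for c in "AB"}
        multi = ["AA", "AB", "BA", "BB", "AAB", "ABB", "BAA", "BBA", "AABB", "BBAA"]
        entries.update({w: 0.08 for w in multi})
        vocab = Vocabulary(entries)
        losses = [WordLoss(w, float(i)) for i, w in enumerate(multi)]
        pruned = prune_vocabulary(vocab, losses, 50)
        kept = {w for w in pruned.entries if len(w) > 1}
        assert kept == set(multi[-5:])

    def test_singletons_survive_and_sum_restored(self):
        vocab = self._uniform_vocab(10)
        pruned = prune_vocabulary(vocab, word_losses(["ACD"], vocab), 30)
        assert {"A", "C", "D"} <= set(pruned.entries)
        assert math.isclose(sum(pruned.entries.values()), 1.0, abs_tol=1e-9)

    def test_invalid_alpha_rejected(self):
        vocab = self._uniform_vocab(5)
        with pytest.raises(SegmentationError):
            prune_vocabulary(vocab, [], 0)


class TestLearnVocabulary:
    def test_target_alphabet_size_returns_singletons_only(self):
        vocab = learn_vocabulary(["ABAB", "ABBA"], target_size=2, seed_size=10)
        assert set(vocab.entries) == {"A", "B"}

    def test_deterministic(self):
        corpus = ["MKVMKV", "MKVA", "AMKV"] * 3
        one = learn_vocabulary(corpus, target_size=6, seed_size=12)
        two = learn_vocabulary(corpus, target_size=6, seed_size=12)
        assert one.entries == two.entries

    def test_recovers_planted_words_in_tiny_corpus(self):
        from bioword.synthetic_data import (
            generate_sequences,
            generate_vocabulary,
            recovery_rate,
        )

        planted = generate_vocabulary(n_words=10, max_word_len=4, seed=5,
                                      singleton_mass=0.05)
        records, _ = generate_sequences(planted, 60, 12, seed=6)
        learned = learn_vocabulary([r.residues for r in records],
                                   target_size=2 * 10 + 20, seed_size=120)
        assert recovery_rate(planted.words, learned) >= 0.8

    def test_final_size_within_target(self):
        corpus = ["MKVAC" * 3, "ACMKV" * 3, "VKM" * 4]
        vocab = learn_vocabulary(corpus, target_size=8, seed_size=20)
        assert len(vocab) <= 8
        assert math.isclose(sum(vocab.entries.values()), 1.0, abs_tol=1e-9)


class TestKmerTokenize:
    def test_three_mer_worked_example(self):
        assert kmer_tokenize("KYMWHKDR", 3, 1) == [
            "KYM", "YMW", "MWH", "WHK", "HKD", "KDR",
        ]

    def test_window_equal_to_length(self):
        assert kmer_tokenize("ACD", 3, 1) == ["ACD"]

    def test_stride_two_count_formula(self):
        tokens = kmer_tokenize("ABCDEF", 2, 2)
        assert tokens == ["AB", "CD", "EF"]
        assert len(tokens) == (6 - 2) // 2 + 1

    def test_k_longer_than_sequence_is_an_error(self):
        with pytest.raises(SegmentationError):
            kmer_tokenize("AC", 3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDE", min_size=1, max_size=30),
           st.integers(1, 5), st.integers(1, 4))
    def test_token_count_law(self, seq, k, stride):
        if k > len(seq):
            with pytest.raises(SegmentationError):
                kmer_tokenize(seq, k, stride)
        else:
            tokens = kmer_tokenize(seq, k, stride)
            assert len(tokens) == (len(seq) - k) // stride + 1
            assert all(len(t) == k for t in tokens)
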