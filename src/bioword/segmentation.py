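"""Data-driven bio-word segmentation with a unigram language model.

A protein sequence is treated as a sentence whose words are unknown.  Under
the unigram model a tokenization s = (s1 ... sN) has probability
P(s) = prod_i p(si), with the word probabilities p(si) summing to 1 over a
vocabulary Phi.  The vocabulary is learned by:

1. seeding a large candidate set with all observed residues plus the most
   frequent residue strings, found by iterated merging of the most frequent
   adjacent token pair (BPE-style);
2. estimating p(si) by EM, maximizing the marginal corpus likelihood
   F = sum_x log sum_{s in X(D_x)} P(s), computed exactly by sum-product
   dynamic programming over each sentence's segmentation lattice;
3. scoring each removable word by the drop in F its removal would cause and
   keeping the top alpha percent, repeating until the target size is reached.

Single-residue words are never pruned, so every sequence stays segmentable.
The most probable segmentation of a sequence is found with the Viterbi
algorithm over the same lattice.  A sliding-window k-mer tokenizer is
provided as the baseline segmentation scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Vocabulary", "Segmentation", "WordLoss", "SegmentationError",
    "seed_vocabulary", "em_estimate", "em_likelihood_trajectory",
    "corpus_log_likelihood", "sentence_log_likelihood",
    "viterbi_segment", "word_losses",
    "prune_vocabulary", "learn_vocabulary", "kmer_tokenize",
]

_NEG_INF = float("-inf")
#: probability floor applied to single-residue words before renormalization,
#: so pruning rounds can never strand an unsegmentable sequence
SINGLETON_FLOOR = 1e-8
#: floor for multi-residue words (all probabilities must stay positive)
MULTI_FLOOR = 1e-12
DEFAULT_MAX_WORD_LEN = 8


class SegmentationError(ValueError):
    """Raised for invalid vocabularies, corpora or unsegmentable input."""


@dataclass(frozen=True)
class Vocabulary:
    """A word set with occurrence probabilities p(si) summing to 1."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise SegmentationError("vocabulary must be non-empty")
        for word, p in self.entries.items():
            if not word:
                raise SegmentationError("vocabulary contains an empty word")
            if not (p > 0):
                raise SegmentationError(f"word {word!r} has non-positive probability {p}")
        total = math.fsum(self.entries.values())
        if abs(total - 1.0) > 1e-9:
            raise SegmentationError(f"vocabulary probabilities sum to {total!r}, not 1")

    @property
    def mandatory_singletons(self) -> frozenset[str]:
        return frozenset(w for w in self.entries if len(w) == 1)

    @property
    def max_word_len(self) -> int:
        return max(len(w) for w in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries


@dataclass(frozen=True)
class Segmentation:
    """An ordered tokenization of one sequence with its log-probability."""

    tokens: tuple[str, ...]
    log_probability: float

    @property
    def sequence(self) -> str:
        return "".join(self.tokens)


@dataclass(frozen=True)
class WordLoss:
    """The drop in marginal likelihood F if *word* were removed."""

    word: str
    loss: float


def _normalize(counts: dict[str, float]) -> dict[str, float]:
    """Floor singleton/multi-residue probabilities and renormalize to 1."""
    floored = {
        w: max(c, SINGLETON_FLOOR if len(w) == 1 else MULTI_FLOOR)
        for w, c in counts.items()
    }
    total = math.fsum(floored.values())
    return {w: c / total for w, c in floored.items()}


def _validate_corpus(corpus: Sequence[str]) -> None:
    if not corpus:
        raise SegmentationError("corpus must be non-empty")
    for i, sent in enumerate(corpus):
        if not sent:
            raise SegmentationError(f"corpus sentence {i} is empty")


def _sentence_edges(
    sentence: str, entries: dict[str, float], max_len: int
) -> list[list[tuple[int, str]]]:
    """For each end position j (1..L), the lattice edges (start, word)."""
    L = len(sentence)
    edges: list[list[tuple[int, str]]] = [[] for _ in range(L + 1)]
    for j in range(1, L + 1):
        row = edges[j]
        for l in range(1, min(max_len, j) + 1):
            w = sentence[j - l : j]
            if w in entries:
                row.append((j - l, w))
    return edges


def _logaddexp(a: float, b: float) -> float:
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


def _forward(
    edges: list[list[tuple[int, str]]], logp: dict[str, float]
) -> list[float]:
    L = len(edges) - 1
    alpha = [_NEG_INF] * (L + 1)
    alpha[0] = 0.0
    for j in range(1, L + 1):
        acc = _NEG_INF
        for i, w in edges[j]:
            if alpha[i] != _NEG_INF:
                acc = _logaddexp(acc, alpha[i] + logp[w])
        alpha[j] = acc
    return alpha


def sentence_log_likelihood(sentence: str, vocab: Vocabulary) -> float:
    """log P(D) = log of the sum of P(s) over all segmentations of *sentence*."""
    logp = {w: math.log(p) for w, p in vocab.entries.items()}
    edges = _sentence_edges(sentence, vocab.entries, vocab.max_word_len)
    ll = _forward(edges, logp)[-1]
    if ll == _NEG_INF:
        raise SegmentationError(f"sentence {sentence!r} is not segmentable with this vocabulary")
    return ll


def corpus_log_likelihood(corpus: Sequence[str], vocab: Vocabulary) -> float:
    """The marginal likelihood F: sum of per-sentence log-likelihoods."""
    _validate_corpus(corpus)
    return math.fsum(sentence_log_likelihood(s, vocab) for s in corpus)


def seed_vocabulary(
    corpus: Sequence[str],
    seed_size: int,
    max_word_len: int = DEFAULT_MAX_WORD_LEN,
) -> Vocabulary:
    """Build the seed vocabulary: all observed residues plus frequent strings.

    Starting from single-residue tokens, the most frequent adjacent token
    pair is merged repeatedly (ties broken toward the lexicographically
    smallest pair; merges are applied left-to-right without overlap) until
    *seed_size* entries exist or no pair occurs more than once.  Initial
    probabilities are proportional to token frequency in the final merged
    tokenization of the corpus.
    """
    _validate_corpus(corpus)
    singles = sorted({c for sent in corpus for c in sent})
    if seed_size < len(singles):
        raise SegmentationError(
            f"seed_size {seed_size} is smaller than the observed alphabet ({len(singles)})"
        )
    tokenized = [list(sent) for sent in corpus]
    words: set[str] = set(singles)

    while len(words) < seed_size:
        pair_counts: dict[tuple[str, str], int] = {}
        for toks in tokenized:
            for a, b in zip(toks, toks[1:]):
                if len(a) + len(b) <= max_word_len:
                    pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
        if not pair_counts:
            break
        best_count = max(pair_counts.values())
        if best_count <= 1:
            break
        best = min(p for p, c in pair_counts.items() if c == best_count)
        merged_word = best[0] + best[1]
        changed = False
        for toks in tokenized:
            i = 0
            out = []
            while i < len(toks):
                if i + 1 < len(toks) and (toks[i], toks[i + 1]) == best:
                    out.append(merged_word)
                    i += 2
                    changed = True
                else:
                    out.append(toks[i])
                    i += 1
            toks[:] = out
        if not changed:
            break
        words.add(merged_word)

    counts: dict[str, float] = {w: 0.0 for w in words}
    for toks in tokenized:
        for t in toks:
            counts[t] += 1.0
    return Vocabulary(_normalize(counts))


def _em_expected_counts(
    corpus_edges: list[list[list[tuple[int, str]]]],
    logp: dict[str, float],
    corpus: Sequence[str],
) -> tuple[dict[str, float], float]:
    """One E-step: expected word counts via forward-backward, plus F."""
    expected: dict[str, float] = {w: 0.0 for w in logp}
    total_ll = 0.0
    for sent, edges in zip(corpus, corpus_edges):
        L = len(edges) - 1
        alpha = _forward(edges, logp)
        ll = alpha[L]
        if ll == _NEG_INF:
            raise SegmentationError(
                f"sentence {sent!r} is not segmentable with this vocabulary"
            )
        total_ll += ll
        beta = [_NEG_INF] * (L + 1)
        beta[L] = 0.0
        # edges indexed by end position; build start-indexed view on the fly
        starts: list[list[tuple[int, str]]] = [[] for _ in range(L + 1)]
        for j in range(1, L + 1):
            for i, w in edges[j]:
                starts[i].append((j, w))
        for i in range(L - 1, -1, -1):
            acc = _NEG_INF
            for j, w in starts[i]:
                if beta[j] != _NEG_INF:
                    acc = _logaddexp(acc, logp[w] + beta[j])
            beta[i] = acc
        for j in range(1, L + 1):
            for i, w in edges[j]:
                if alpha[i] != _NEG_INF and beta[j] != _NEG_INF:
                    expected[w] += math.exp(alpha[i] + logp[w] + beta[j] - ll)
    return expected, total_ll


def _em_loop(
    corpus: Sequence[str],
    entries: dict[str, float],
    max_iterations: int,
    tolerance: float,
) -> tuple[dict[str, float], list[float]]:
    max_len = max(len(w) for w in entries)
    corpus_edges = [_sentence_edges(sent, entries, max_len) for sent in corpus]
    history: list[float] = []
    for it in range(max_iterations + 1):
        logp = {w: math.log(p) for w, p in entries.items()}
        expected, ll = _em_expected_counts(corpus_edges, logp, corpus)
        # ll is F of the *current* entries; convergence is judged before the
        # M-step so the converged parameters are returned unchanged
        if history and (ll - history[-1] < tolerance or it == max_iterations):
            history.append(ll)
            break
        history.append(ll)
        entries = _normalize(expected)
    return entries, history


def em_estimate(
    corpus: Sequence[str],
    vocab: Vocabulary,
    max_iterations: int = 10,
    tolerance: float = 1e-6,
) -> Vocabulary:
    """Re-estimate word probabilities by EM on the marginal likelihood F.

    Each iteration computes expected word counts with forward-backward over
    every sentence lattice (E) and renormalizes them into probabilities (M).
    F is non-decreasing across iterations; iteration stops after
    *max_iterations* or when F improves by less than *tolerance*.
    """
    _validate_corpus(corpus)
    if max_iterations < 1:
        raise SegmentationError("max_iterations must be >= 1")
    entries, _ = _em_loop(corpus, dict(vocab.entries), max_iterations, tolerance)
    return Vocabulary(entries)


def em_likelihood_trajectory(
    corpus: Sequence[str],
    vocab: Vocabulary,
    iterations: int,
) -> list[float]:
    """F evaluated at the start of each EM iteration (length iterations + 1).

    Under EM this sequence is non-decreasing, up to the tiny probability
    floors applied in the M-step.
    """
    _validate_corpus(corpus)
    if iterations < 1:
        raise SegmentationError("iterations must be >= 1")
    _, history = _em_loop(corpus, dict(vocab.entries), iterations, -math.inf)
    return history


def viterbi_segment(sequence: str, vocab: Vocabulary) -> Segmentation:
    """The most probable segmentation s* = argmax P(s) over all candidates.

    Dynamic programming over the segment lattice, linear in sequence length
    times the maximum word length.  Ties are broken toward the segmentation
    with fewer tokens, then toward the longest final word at each position
    (leftmost-longest).
    """
    if not sequence:
        raise SegmentationError("cannot segment an empty sequence")
    logp = {w: math.log(p) for w, p in vocab.entries.items()}
    edges = _sentence_edges(sequence, vocab.entries, vocab.max_word_len)
    L = len(sequence)
    # best[j] = (log-probability, -token count, start of final word)
    best: list[tuple[float, int, int]] = [(_NEG_INF, 0, -1)] * (L + 1)
    best[0] = (0.0, 0, -1)
    for j in range(1, L + 1):
        for i, w in edges[j]:  # i ascending: earliest start wins exact ties
            lp, neg_n, _ = best[i]
            if lp == _NEG_INF:
                continue
            cand = (lp + logp[w], neg_n - 1)
            if cand > (best[j][0], best[j][1]):
                best[j] = (cand[0], cand[1], i)
    if best[L][0] == _NEG_INF:
        raise SegmentationError(
            f"sequence {sequence!r} is not segmentable with this vocabulary"
        )
    tokens: list[str] = []
    j = L
    while j > 0:
        i = best[j][2]
        tokens.append(sequence[i:j])
        j = i
    tokens.reverse()
    return Segmentation(tuple(tokens), best[L][0])


def word_losses(corpus: Sequence[str], vocab: Vocabulary) -> list[WordLoss]:
    """Score every word by the change in F caused by removing it.

    For a multi-residue word w, loss(w) = sum over the sentences whose
    lattices use w of [log P(D | Phi) - log P(D | Phi without w)]; sentences
    not containing w contribute exactly zero.  Probabilities are held fixed
    (no renormalization), so a word absent from every lattice has loss 0.
    Single-residue words are never removable and get infinite loss.
    """
    _validate_corpus(corpus)
    logp = {w: math.log(p) for w, p in vocab.entries.items()}
    max_len = vocab.max_word_len
    corpus_edges = [_sentence_edges(sent, vocab.entries, max_len) for sent in corpus]
    base_ll: list[float] = []
    word_to_sents: dict[str, list[int]] = {w: [] for w in vocab.entries}
    for idx, (sent, edges) in enumerate(zip(corpus, corpus_edges)):
        ll = _forward(edges, logp)[-1]
        if ll == _NEG_INF:
            raise SegmentationError(
                f"sentence {sent!r} is not segmentable with this vocabulary"
            )
        base_ll.append(ll)
        present: set[str] = set()
        for row in edges:
            for _, w in row:
                present.add(w)
        for w in present:
            word_to_sents[w].append(idx)

    losses: list[WordLoss] = []
    for w in vocab.entries:
        if len(w) == 1:
            losses.append(WordLoss(w, math.inf))
            continue
        sents = word_to_sents[w]
        if not sents:
            losses.append(WordLoss(w, 0.0))
            continue
        loss = 0.0
        for idx in sents:
            pruned_edges = [
                [(i, u) for i, u in row if u != w] for row in corpus_edges[idx]
            ]
            ll_without = _forward(pruned_edges, logp)[-1]
            loss += base_ll[idx] - ll_without  # +inf if the sentence needs w
        losses.append(WordLoss(w, loss))
    return losses


def _prune_to_count(
    vocab: Vocabulary, losses: Iterable[WordLoss], keep: int
) -> Vocabulary:
    """Keep the *keep* highest-loss multi-residue words plus all singletons."""
    loss_map = {wl.word: wl.loss for wl in losses}
    multi = [w for w in vocab.entries if len(w) > 1]
    missing = [w for w in multi if w not in loss_map]
    if missing:
        raise SegmentationError(f"no loss computed for word(s) {missing[:5]}")
    ranked = sorted(multi, key=lambda w: (-loss_map[w], w))
    kept = set(ranked[: max(keep, 0)])
    counts = {
        w: p for w, p in vocab.entries.items() if len(w) == 1 or w in kept
    }
    return Vocabulary(_normalize(counts))


def prune_vocabulary(
    vocab: Vocabulary,
    losses: Iterable[WordLoss],
    alpha_keep_percent: float,
) -> Vocabulary:
    """One pruning round: keep the top alpha% of removable words by loss.

    Retains ceil(alpha% of the multi-residue words) with the highest loss
    plus every single-residue word, then renormalizes.  alpha applies to
    removable (multi-residue) words only.
    """
    if not (0 < alpha_keep_percent <= 100):
        raise SegmentationError("alpha_keep_percent must lie in (0, 100]")
    losses = list(losses)
    n_multi = sum(1 for w in vocab.entries if len(w) > 1)
    keep = math.ceil(alpha_keep_percent / 100.0 * n_multi)
    return _prune_to_count(vocab, losses, keep)


def learn_vocabulary(
    corpus: Sequence[str],
    target_size: int,
    seed_size: int,
    alpha_keep_percent: float = 70.0,
    em_iterations: int = 2,
    max_word_len: int = DEFAULT_MAX_WORD_LEN,
    em_tolerance: float = 1e-4,
) -> Vocabulary:
    """Learn a bio-word vocabulary of at most *target_size* entries.

    Seeds a large candidate vocabulary, then alternates EM estimation of the
    word probabilities with loss-based pruning (keep top alpha% per round,
    never dropping below the target) until the entry count is <= target_size.
    Deterministic given the corpus and parameters.
    """
    _validate_corpus(corpus)
    alphabet = {c for sent in corpus for c in sent}
    if target_size < len(alphabet):
        raise SegmentationError(
            f"target_size {target_size} is smaller than the observed alphabet ({len(alphabet)})"
        )
    if seed_size < target_size:
        raise SegmentationError("seed_size must be >= target_size")
    vocab = seed_vocabulary(corpus, seed_size, max_word_len=max_word_len)
    n_single = len(vocab.mandatory_singletons)
    while True:
        vocab = em_estimate(corpus, vocab, max_iterations=em_iterations,
                            tolerance=em_tolerance)
        n_multi = len(vocab) - n_single
        if len(vocab) <= target_size:
            return vocab
        losses = word_losses(corpus, vocab)
        keep = math.ceil(alpha_keep_percent / 100.0 * n_multi)
        keep = min(keep, n_multi - 1)  # guarantee progress
        keep = max(keep, target_size - n_single, 0)  # never overshoot the target
        vocab = _prune_to_count(vocab, losses, keep)


def kmer_tokenize(sequence: str, k: int, stride: int = 1) -> list[str]:
    """Sliding-window k-mer baseline: floor((L - k)/stride) + 1 tokens.

    The i-th token is the length-k substring starting at offset i*stride.
    ``k > len(sequence)`` is an error rather than an empty list, so that
    downstream vector averaging can never silently receive nothing.
    """
    if k < 1 or stride < 1:
        raise SegmentationError("k and stride must be positive")
    if k > len(sequence):
        raise SegmentationError(
            f"k={k} exceeds sequence length {len(sequence)}"
        )
    return [sequence[i : i + k] for i in range(0, len(sequence) - k + 1, stride)]
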