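"""Synthetic corpora and interaction datasets with known ground truth.

The generator realizes the statistical assumptions the pipeline itself
makes, so every stage can be scored against a planted truth without any
database download:

* a planted vocabulary of multi-residue words with Dirichlet-distributed
  occurrence probabilities (words are generated so that none is a substring
  of another, making recovery scoring unambiguous);
* sequences built by concatenating i.i.d. word draws (the unigram
  assumption), with a small probability mass on single residues as noise;
* a planted interaction rule: the words are partitioned into latent modules,
  each protein's words are drawn mostly from its own module, and a pair
  interacts iff both members contain at least ``threshold`` words of the
  same module.  Labels are always recomputed from this predicate, never
  assigned.

Ground truth (segmentations, module assignments, the rule) is retained
alongside every generated artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from bioword.io_formats import CANONICAL_AA, LabeledPair, ProteinRecord

__all__ = [
    "PlantedVocabulary", "PlantedInteractionRule", "SyntheticError",
    "generate_vocabulary", "generate_sequences", "make_rule",
    "generate_interaction_dataset", "rule_label", "recovery_rate",
]


class SyntheticError(ValueError):
    """Raised for impossible generator parameters or degenerate output."""


@dataclass(frozen=True)
class PlantedVocabulary:
    """Planted multi-residue words with occurrence probabilities."""

    words: tuple[str, ...]
    probabilities: np.ndarray
    singleton_mass: float

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=np.float64)
        object.__setattr__(self, "probabilities", probs)
        if len(self.words) != len(probs):
            raise SyntheticError("one probability per word is required")
        if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs <= 0):
            raise SyntheticError("word probabilities must be positive and sum to 1")
        if not (0 <= self.singleton_mass < 1):
            raise SyntheticError("singleton_mass must lie in [0, 1)")
        if len(set(self.words)) != len(self.words):
            raise SyntheticError("planted words must be distinct")


@dataclass(frozen=True)
class PlantedInteractionRule:
    """Partition of the planted words into latent modules plus a count rule.

    A pair interacts iff, for some module, both sequences contain at least
    ``threshold`` occurrences of that module's words.
    """

    modules: tuple[frozenset[str], ...]
    threshold: int

    def __post_init__(self) -> None:
        if len(self.modules) < 2:
            raise SyntheticError("at least two latent modules are required")
        if self.threshold < 1:
            raise SyntheticError("threshold must be >= 1")
        all_words = [w for m in self.modules for w in m]
        if len(all_words) != len(set(all_words)):
            raise SyntheticError("modules must partition the words (no overlap)")


def generate_vocabulary(
    n_words: int = 50,
    max_word_len: int = 6,
    dirichlet_concentration: float = 5.0,
    seed: int = 0,
    min_word_len: int = 2,
    singleton_mass: float = 0.05,
) -> PlantedVocabulary:
    """Sample a planted vocabulary, reproducible under *seed*.

    Word lengths are uniform in [min_word_len, max_word_len]; rejection
    sampling guarantees that no word is a substring of any other.
    """
    if n_words < 2:
        raise SyntheticError("n_words must be >= 2")
    if not (2 <= min_word_len <= max_word_len):
        raise SyntheticError("need 2 <= min_word_len <= max_word_len")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(CANONICAL_AA))
    words: list[str] = []
    attempts = 0
    while len(words) < n_words:
        attempts += 1
        if attempts > 1000 * n_words:
            raise SyntheticError(
                "could not generate the requested number of substring-free words"
            )
        length = int(rng.integers(min_word_len, max_word_len + 1))
        cand = "".join(rng.choice(alphabet, size=length))
        if any(cand in w or w in cand for w in words):
            continue
        words.append(cand)
    probs = rng.dirichlet(np.full(n_words, dirichlet_concentration))
    probs = probs / probs.sum()
    return PlantedVocabulary(tuple(words), probs, singleton_mass)


def _draw_tokens(
    vocab: PlantedVocabulary,
    n_tokens: int,
    rng: np.random.Generator,
    word_probs: np.ndarray | None = None,
) -> list[str]:
    probs = vocab.probabilities if word_probs is None else word_probs
    tokens: list[str] = []
    for _ in range(n_tokens):
        if vocab.singleton_mass > 0 and rng.random() < vocab.singleton_mass:
            tokens.append(CANONICAL_AA[int(rng.integers(len(CANONICAL_AA)))])
        else:
            tokens.append(vocab.words[int(rng.choice(len(vocab.words), p=probs))])
    return tokens


def generate_sequences(
    vocab: PlantedVocabulary,
    n_sequences: int,
    words_per_sequence: int,
    seed: int = 0,
    id_prefix: str = "syn",
) -> tuple[list[ProteinRecord], dict[str, list[str]]]:
    """Concatenate i.i.d. word draws into sequences; ground truth retained.

    Returns the records plus a mapping id -> true token list.
    """
    if n_sequences < 1 or words_per_sequence < 1:
        raise SyntheticError("n_sequences and words_per_sequence must be positive")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth: dict[str, list[str]] = {}
    for i in range(n_sequences):
        tokens = _draw_tokens(vocab, words_per_sequence, rng)
        pid = f"{id_prefix}{i:05d}"
        records.append(ProteinRecord(pid, "".join(tokens)))
        truth[pid] = tokens
    return records, truth


def make_rule(
    vocab: PlantedVocabulary,
    n_modules: int = 2,
    threshold: int = 4,
    seed: int = 0,
) -> PlantedInteractionRule:
    """Partition the planted words into *n_modules* latent groups."""
    if n_modules < 2 or n_modules > len(vocab.words):
        raise SyntheticError("need 2 <= n_modules <= number of planted words")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(vocab.words))
    modules: list[set[str]] = [set() for _ in range(n_modules)]
    for pos, widx in enumerate(order):
        modules[pos % n_modules].add(vocab.words[widx])
    return PlantedInteractionRule(tuple(frozenset(m) for m in modules), threshold)


def rule_label(
    rule: PlantedInteractionRule,
    tokens_a: Sequence[str],
    tokens_b: Sequence[str],
) -> int:
    """Evaluate the planted predicate on two ground-truth token lists."""
    for module in rule.modules:
        count_a = sum(1 for t in tokens_a if t in module)
        if count_a < rule.threshold:
            continue
        count_b = sum(1 for t in tokens_b if t in module)
        if count_b >= rule.threshold:
            return 1
    return 0


def generate_interaction_dataset(
    vocab: PlantedVocabulary,
    rule: PlantedInteractionRule,
    n_pairs: int,
    seed: int = 0,
    n_proteins: int | None = None,
    words_per_sequence: int = 25,
    module_purity: float = 0.95,
) -> tuple[list[ProteinRecord], list[LabeledPair], dict[str, list[str]]]:
    """A labeled interaction dataset driven by the planted rule.

    Each protein is assigned a latent module and draws a fraction
    *module_purity* of its (non-singleton) words from that module.  Pairs
    are sampled half within and half across modules so both classes appear;
    every label is computed by :func:`rule_label` on the true tokens.
    """
    if n_pairs < 2:
        raise SyntheticError("n_pairs must be >= 2")
    if not (0.5 < module_purity <= 1.0):
        raise SyntheticError("module_purity must lie in (0.5, 1]")
    rng = np.random.default_rng(seed)
    n_modules = len(rule.modules)
    if n_proteins is None:
        n_proteins = max(4 * n_modules, int(0.4 * n_pairs))

    word_index = {w: i for i, w in enumerate(vocab.words)}
    module_probs: list[np.ndarray] = []
    for module in rule.modules:
        tilt = np.full(len(vocab.words), 0.0)
        for w, i in word_index.items():
            base = vocab.probabilities[i]
            tilt[i] = base * (module_purity if w in module else 1.0 - module_purity)
        module_probs.append(tilt / tilt.sum())

    records: list[ProteinRecord] = []
    truth: dict[str, list[str]] = {}
    assignment: list[int] = []
    per_module: list[list[int]] = [[] for _ in range(n_modules)]
    for i in range(n_proteins):
        m = i % n_modules
        tokens = _draw_tokens(vocab, words_per_sequence, rng,
                              word_probs=module_probs[m])
        pid = f"prot{i:05d}"
        records.append(ProteinRecord(pid, "".join(tokens)))
        truth[pid] = tokens
        assignment.append(m)
        per_module[m].append(i)

    pairs: list[LabeledPair] = []
    seen: set[tuple[int, int]] = set()
    attempts = 0
    while len(pairs) < n_pairs:
        attempts += 1
        if attempts > 100 * n_pairs:
            raise SyntheticError("could not sample enough distinct pairs")
        if rng.random() < 0.5:
            m = int(rng.integers(n_modules))
            a, b = rng.choice(per_module[m], size=2, replace=False)
        else:
            m1, m2 = rng.choice(n_modules, size=2, replace=False)
            a = per_module[m1][int(rng.integers(len(per_module[m1])))]
            b = per_module[m2][int(rng.integers(len(per_module[m2])))]
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        ra, rb = records[int(a)], records[int(b)]
        label = rule_label(rule, truth[ra.id], truth[rb.id])
        pairs.append(LabeledPair(ra.id, rb.id, label))

    n_pos = sum(p.label for p in pairs)
    if n_pos == 0 or n_pos == len(pairs):
        raise SyntheticError(
            f"degenerate rule: {n_pos}/{len(pairs)} positives; adjust the "
            "threshold, purity or words_per_sequence"
        )
    return records, pairs, truth


def recovery_rate(planted: Sequence[str], learned_vocab) -> float:
    """Fraction of planted multi-residue words present in a learned vocabulary."""
    planted = [w for w in planted if len(w) > 1]
    if not planted:
        raise SyntheticError("no multi-residue planted words to score")
    hits = sum(1 for w in planted if w in learned_vocab.entries)
    return hits / len(planted)
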