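"""Skip-gram word embeddings and Bio2Vec sequence vectors.

Each bio-word w carries an input vector v_w and an output vector v'_w.  The
skip-gram objective maximizes the average log-probability of context words
within a window of c positions around each center word, where
P(w_O | w_I) = softmax(v'_{w_O} . v_{w_I}) over the lexicon.  Training uses
the negative-sampling approximation: each observed (center, context) pair is
discriminated logistically against k noise words drawn from the unigram
distribution raised to the 3/4 power.

A protein sequence segmented into N words is represented by the mean of its
word input vectors (the 1/N-scaled sum), so the sequence vector has the same
dimension as the word vectors and its scale does not grow with length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TokenizedCorpus", "EmbeddingMatrix", "SequenceVector", "EmbeddingError",
    "extract_training_pairs", "softmax_log_prob", "train_skipgram",
    "sequence_vector", "negative_sampling_loss_and_grads",
]


class EmbeddingError(ValueError):
    """Raised for invalid corpora, lexica or vectorization input."""


@dataclass
class TokenizedCorpus:
    """Segmented sentences plus their distinct word set (the lexicon)."""

    sentences: list[list[str]]
    lexicon: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.sentences:
            raise EmbeddingError("tokenized corpus must be non-empty")
        seen: dict[str, None] = {}
        for sent in self.sentences:
            if not sent:
                raise EmbeddingError("tokenized corpus contains an empty sentence")
            for tok in sent:
                seen.setdefault(tok, None)
        self.lexicon = sorted(seen)

    @property
    def lexicon_size(self) -> int:
        return len(self.lexicon)


@dataclass
class EmbeddingMatrix:
    """Input and output vector tables over a lexicon of W words."""

    words: list[str]
    input_vectors: np.ndarray  # (W, n)
    output_vectors: np.ndarray  # (W, n)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.input_vectors = np.asarray(self.input_vectors, dtype=np.float64)
        self.output_vectors = np.asarray(self.output_vectors, dtype=np.float64)
        W = len(self.words)
        if W == 0:
            raise EmbeddingError("embedding matrix must cover at least one word")
        for name, table in (("input", self.input_vectors), ("output", self.output_vectors)):
            if table.ndim != 2 or table.shape[0] != W:
                raise EmbeddingError(f"{name} table must have one row per word")
            if not np.all(np.isfinite(table)):
                raise EmbeddingError(f"{name} table contains non-finite components")
        if self.input_vectors.shape[1] != self.output_vectors.shape[1]:
            raise EmbeddingError("input and output tables disagree on dimension")
        self.index = {w: i for i, w in enumerate(self.words)}
        if len(self.index) != W:
            raise EmbeddingError("embedding words must be distinct")

    @property
    def dimension(self) -> int:
        return self.input_vectors.shape[1]

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.input_vectors[self.index[word]]
        except KeyError:
            raise EmbeddingError(f"word {word!r} not in lexicon") from None


@dataclass(frozen=True)
class SequenceVector:
    """The fixed-length Bio2Vec representation of one protein."""

    values: np.ndarray
    source_id: str = ""


def extract_training_pairs(
    sentence: Sequence[str], context_window: int
) -> list[tuple[str, str]]:
    """All (center, context) pairs with |offset| <= context_window, offset != 0."""
    if context_window < 1:
        raise EmbeddingError("context_window must be >= 1")
    pairs: list[tuple[str, str]] = []
    T = len(sentence)
    for t in range(T):
        for j in range(-context_window, context_window + 1):
            if j == 0:
                continue
            u = t + j
            if 0 <= u < T:
                pairs.append((sentence[t], sentence[u]))
    return pairs


def softmax_log_prob(target: str, center: str, matrix: EmbeddingMatrix) -> float:
    """log P(target | center) under the full softmax over the lexicon.

    Numerically stabilized by max-subtraction.
    """
    if center not in matrix.index:
        raise EmbeddingError(f"center word {center!r} not in lexicon")
    if target not in matrix.index:
        raise EmbeddingError(f"target word {target!r} not in lexicon")
    scores = matrix.output_vectors @ matrix.input_vectors[matrix.index[center]]
    scores = scores - scores.max()
    log_z = np.log(np.exp(scores).sum())
    return float(scores[matrix.index[target]] - log_z)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def negative_sampling_loss_and_grads(
    v_center: np.ndarray,
    v_out: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Per-pair negative-sampling loss and its analytic gradients.

    ``v_out`` stacks the output vectors of the true context word and the k
    noise words; ``labels`` is 1 for the true pair and 0 for noise.  The loss
    is the summed logistic loss; returns (loss, grad wrt v_center, grad wrt
    each row of v_out).
    """
    scores = v_out @ v_center
    probs = _sigmoid(scores)
    eps = 1e-12
    loss = -float(
        np.sum(labels * np.log(probs + eps) + (1 - labels) * np.log(1 - probs + eps))
    )
    g = probs - labels  # d loss / d score
    grad_center = g @ v_out
    grad_out = np.outer(g, v_center)
    return loss, grad_center, grad_out


def train_skipgram(
    corpus: TokenizedCorpus,
    dimension: int = 64,
    context_window: int = 5,
    negative_samples: int = 5,
    epochs: int = 5,
    learning_rate: float = 0.025,
    random_seed: int = 0,
) -> EmbeddingMatrix:
    """Train skip-gram with negative sampling by sequential SGD.

    Noise words are drawn from unigram^(3/4); the learning rate decays
    linearly over the total number of updates.  Input vectors start uniform
    in [-0.5/n, 0.5/n], output vectors at zero.  Fully reproducible given
    *random_seed*.
    """
    if dimension < 1 or context_window < 1 or negative_samples < 1 or epochs < 1:
        raise EmbeddingError("dimension, context_window, negative_samples and epochs must be >= 1")
    words = corpus.lexicon
    W = len(words)
    if W < 2:
        raise EmbeddingError("lexicon must contain at least 2 words")
    index = {w: i for i, w in enumerate(words)}

    counts = np.zeros(W, dtype=np.float64)
    centers: list[int] = []
    contexts: list[int] = []
    for sent in corpus.sentences:
        ids = [index[t] for t in sent]
        for i in ids:
            counts[i] += 1
        T = len(ids)
        for t in range(T):
            lo = max(0, t - context_window)
            hi = min(T, t + context_window + 1)
            for u in range(lo, hi):
                if u != t:
                    centers.append(ids[t])
                    contexts.append(ids[u])
    centers_arr = np.asarray(centers, dtype=np.int64)
    contexts_arr = np.asarray(contexts, dtype=np.int64)
    n_pairs = len(centers_arr)

    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(random_seed)
    W_in = rng.uniform(-0.5 / dimension, 0.5 / dimension, size=(W, dimension))
    W_out = np.zeros((W, dimension))

    if n_pairs == 0:
        # single-token sentences only: nothing to train on
        return EmbeddingMatrix(list(words), W_in, W_out)

    k = negative_samples
    labels = np.zeros(k + 1)
    labels[0] = 1.0
    total_updates = n_pairs * epochs
    step = 0
    for _ in range(epochs):
        negs = np.searchsorted(noise_cdf, rng.random((n_pairs, k)))
        for p in range(n_pairs):
            lr = learning_rate * max(1.0 - step / total_updates, 1e-4)
            c = centers_arr[p]
            idx = np.empty(k + 1, dtype=np.int64)
            idx[0] = contexts_arr[p]
            idx[1:] = negs[p]
            h = W_in[c]
            g = (_sigmoid(W_out[idx] @ h) - labels) * lr
            grad_h = g @ W_out[idx]
            np.subtract.at(W_out, idx, np.outer(g, h))
            W_in[c] -= grad_h
            step += 1
    return EmbeddingMatrix(list(words), W_in, W_out)


def sequence_vector(
    tokens: Sequence[str], matrix: EmbeddingMatrix, source_id: str = ""
) -> SequenceVector:
    """The Bio2Vec representation: the mean of the tokens' input vectors.

    Tokens missing from the lexicon are skipped; if every token is unknown
    the sequence has no representation and an error is raised.
    """
    if not tokens:
        raise EmbeddingError("cannot vectorize an empty token list")
    rows = [matrix.index[t] for t in tokens if t in matrix.index]
    if not rows:
        raise EmbeddingError(
            f"no token of sequence {source_id!r} is present in the lexicon"
        )
    values = matrix.input_vectors[rows].mean(axis=0)
    return SequenceVector(values=values, source_id=source_id)
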