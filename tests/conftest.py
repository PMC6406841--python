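import math

import pytest

from bioword.segmentation import Vocabulary


@pytest.fixture
def singleton_vocab():
    return Vocabulary({"A": 0.5, "B": 0.3, "C": 0.2})


@pytest.fixture
def mixed_vocab():
    return Vocabulary({"A": 0.4, "B": 0.1, "AB": 0.5})


def enumerate_segmentations(sequence, entries):
    """All tokenizations of *sequence* whose tokens are in *entries*."""
    if not sequence:
        yield []
        return
    for l in range(1, len(sequence) + 1):
        head = sequence[:l]
        if head in entries:
            for rest in enumerate_segmentations(sequence[l:], entries):
                yield [head] + rest


def brute_force_best_log_prob(sequence, entries):
    """Max log P(s) over all segmentations, by exhaustive enumeration."""
    best = -math.inf
    for tokens in enumerate_segmentations(sequence, entries):
        lp = sum(math.log(entries[t]) for t in tokens)
        best = max(best, lp)
    return best


def brute_force_marginal(sequence, entries):
    """log of the summed probability over all segmentations."""
    total = 0.0
    for tokens in enumerate_segmentations(sequence, entries):
        total += math.prod(entries[t] for t in tokens)
    return math.log(total) if total > 0 else -math.inf
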