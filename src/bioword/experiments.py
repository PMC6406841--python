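"""Self-contained synthetic experiments scoring every pipeline stage.

These functions generate data with :mod:`bioword.synthetic_data`, run the
pipeline, and measure recovery and prediction quality against the planted
ground truth.  The default problem sizes are the package's desk-scale study
conditions: 50 planted words, 2000 labeled pairs, 32-dimensional embeddings.
Vocabulary learning uses a 300-sequence subsample of the corpus (word
statistics saturate well before that; segmentation and all later stages
still cover every sequence).
"""

from __future__ import annotations

import numpy as np

from bioword.classifier import predict_pairs, train_classifier
from bioword.embedding import TokenizedCorpus, train_skipgram
from bioword.evaluation import confusion, metrics, roc_auc, split_dataset
from bioword.io_formats import LabeledPair
from bioword.pipeline import pair_features, segment_records, vectorize_records
from bioword.segmentation import learn_vocabulary
from bioword.synthetic_data import (
    generate_interaction_dataset,
    generate_sequences,
    generate_vocabulary,
    make_rule,
    recovery_rate,
)

__all__ = ["segmentation_recovery_experiment", "endtoend_experiment"]


def segmentation_recovery_experiment(
    seed: int = 1,
    n_words: int = 50,
    n_sequences: int = 300,
    words_per_sequence: int = 25,
    seed_vocab_size: int = 400,
    max_word_len: int = 8,
) -> dict:
    """Learn a vocabulary from a planted-word corpus and score word recovery.

    The learner's target size is twice the planted vocabulary size.  Returns
    the recovery fraction and the sizes involved.
    """
    vocab = generate_vocabulary(n_words=n_words, max_word_len=6, seed=seed)
    records, _ = generate_sequences(vocab, n_sequences, words_per_sequence,
                                    seed=seed + 1)
    corpus = [r.residues for r in records]
    learned = learn_vocabulary(
        corpus,
        target_size=2 * n_words,
        seed_size=seed_vocab_size,
        max_word_len=max_word_len,
    )
    return {
        "recovery": recovery_rate(vocab.words, learned),
        "n_planted": n_words,
        "learned_size": len(learned),
        "n_sequences": n_sequences,
    }


def endtoend_experiment(
    seed: int = 1,
    n_pairs: int = 2000,
    n_words: int = 50,
    embedding_dim: int = 32,
    words_per_sequence: int = 25,
    vocab_corpus_size: int = 300,
    seed_vocab_size: int = 400,
    context_window: int = 5,
    embedding_epochs: int = 5,
) -> dict:
    """Full segment -> embed -> classify run on planted-rule data.

    Trains on the 0.72/0.18 train/validation split, evaluates on the held-out
    tenth, and repeats classifier training with globally permuted labels as a
    no-signal control.  Also scores planted-word recovery of the learned
    vocabulary.  Returns a flat dict of the measured quantities.
    """
    planted = generate_vocabulary(n_words=n_words, max_word_len=6, seed=seed)
    rule = make_rule(planted, n_modules=2, threshold=4, seed=seed + 1)
    records, pairs, truth = generate_interaction_dataset(
        planted, rule, n_pairs=n_pairs, seed=seed + 2,
        words_per_sequence=words_per_sequence,
    )

    corpus = [r.residues for r in records[:vocab_corpus_size]]
    vocab = learn_vocabulary(corpus, target_size=2 * n_words,
                             seed_size=seed_vocab_size)
    recovery = recovery_rate(planted.words, vocab)

    tokens_by_id = segment_records(records, vocab)
    matrix = train_skipgram(
        TokenizedCorpus([tokens_by_id[r.id] for r in records]),
        dimension=embedding_dim,
        context_window=context_window,
        epochs=embedding_epochs,
        random_seed=seed + 3,
    )
    vectors = vectorize_records(tokens_by_id, matrix)

    def fit_and_score(pair_list: list[LabeledPair]) -> dict:
        split = split_dataset(pair_list, seed=seed + 4)
        model = train_classifier(
            pair_features(split.train, vectors),
            pair_features(split.validation, vectors),
            random_seed=seed + 5,
        )
        probs = predict_pairs(model, pair_features(split.test, vectors,
                                                   labeled=False))
        labels = [p.label for p in split.test]
        report = metrics(confusion(labels, (probs >= 0.5).astype(int).tolist()))
        _, auc = roc_auc(probs, labels)
        return {"auc": auc, "report": report, "epochs": model.history["epochs_run"]}

    true_run = fit_and_score(pairs)

    rng = np.random.default_rng(seed + 6)
    permuted_labels = rng.permutation([p.label for p in pairs])
    permuted_pairs = [
        LabeledPair(p.id_a, p.id_b, int(lab))
        for p, lab in zip(pairs, permuted_labels)
    ]
    control_run = fit_and_score(permuted_pairs)

    report = true_run["report"]
    return {
        "recovery": recovery,
        "n_pairs": n_pairs,
        "n_proteins": len(records),
        "positive_fraction": sum(p.label for p in pairs) / len(pairs),
        "test_auc": true_run["auc"],
        "test_accuracy": report.accuracy,
        "test_sensitivity": report.sensitivity,
        "test_precision": report.precision,
        "test_mcc": report.mcc,
        "epochs_run": true_run["epochs"],
        "permuted_auc": control_run["auc"],
    }
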