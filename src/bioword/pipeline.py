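"""End-to-end orchestration: the two-stage workflow behind the CLI.

Stage one builds the representation (vocabulary learning, segmentation,
skip-gram training, sequence vectorization); stage two trains and evaluates
the pair classifier.  Every stage writes its artifact to the output
directory and is recorded, with a content digest, in a JSON manifest, so a
run can be reproduced or resumed stage by stage.

Per-stage seeds are derived from the master seed by a fixed counter scheme:
``stage_seed(master, k) = (master * 1009 + k) mod 2**31`` for stage index k.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from bioword.classifier import (
    PairFeature,
    make_pair_feature,
    predict_pairs,
    save_model,
    train_classifier,
)
from bioword.embedding import (
    EmbeddingMatrix,
    SequenceVector,
    TokenizedCorpus,
    sequence_vector,
    train_skipgram,
)
from bioword.evaluation import confusion, metrics, roc_auc, split_dataset
from bioword.io_formats import (
    LabeledPair,
    ProteinRecord,
    RunConfig,
    read_fasta,
    read_pairs,
    write_config,
    write_embeddings,
    write_vocabulary,
)
from bioword.segmentation import Vocabulary, learn_vocabulary, viterbi_segment

__all__ = [
    "stage_seed", "segment_records", "vectorize_records", "pair_features",
    "run_pipeline", "PipelineError",
]

STAGES = (
    "ingest", "learn_vocab", "segment", "embed",
    "vectorize", "train", "evaluate",
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed (counter scheme, always below 2**31)."""
    return (master_seed * 1009 + stage_index) % (2**31)


def segment_records(
    records: Sequence[ProteinRecord], vocab: Vocabulary
) -> dict[str, list[str]]:
    """Viterbi-segment every record; returns id -> token list."""
    return {rec.id: list(viterbi_segment(rec.residues, vocab).tokens)
            for rec in records}


def vectorize_records(
    tokens_by_id: dict[str, list[str]], matrix: EmbeddingMatrix
) -> dict[str, SequenceVector]:
    return {pid: sequence_vector(toks, matrix, source_id=pid)
            for pid, toks in tokens_by_id.items()}


def pair_features(
    pairs: Sequence[LabeledPair],
    vectors: dict[str, SequenceVector],
    labeled: bool = True,
) -> list[PairFeature]:
    return [
        make_pair_feature(
            vectors[p.id_a].values, vectors[p.id_b].values,
            p.label if labeled else None,
        )
        for p in pairs
    ]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(
    config: RunConfig,
    fasta_path: str | Path,
    pairs_path: str | Path,
    out_dir: str | Path,
    vocab_corpus_limit: int | None = None,
) -> dict:
    """Run every stage in order and write a manifest of the artifacts.

    ``vocab_corpus_limit`` optionally caps the number of sequences used for
    vocabulary learning (segmentation and all later stages still cover the
    full input).  Returns the manifest dictionary, also written to
    ``manifest.json`` in *out_dir*.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    seeds = {name: stage_seed(config.random_seed, i) for i, name in enumerate(STAGES)}

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            raise PipelineError(name, str(exc)) from exc

    def ingest():
        records = read_fasta(fasta_path)
        pairs = read_pairs(pairs_path, records)
        return records, pairs

    records, pairs = run_stage("ingest", ingest)

    def learn():
        corpus = [r.residues for r in records]
        if vocab_corpus_limit is not None:
            corpus = corpus[:vocab_corpus_limit]
        vocab = learn_vocabulary(
            corpus,
            target_size=config.vocab_size,
            seed_size=config.seed_vocab_size,
            alpha_keep_percent=config.alpha_keep_percent,
            max_word_len=config.max_word_len,
        )
        path = out / "vocabulary.tsv"
        write_vocabulary(vocab, path)
        artifacts["vocabulary"] = path
        return vocab

    vocab = run_stage("learn_vocab", learn)

    def segment():
        tokens = segment_records(records, vocab)
        path = out / "tokens.txt"
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f"{rec.id}\t{' '.join(tokens[rec.id])}\n")
        artifacts["tokens"] = path
        return tokens

    tokens_by_id = run_stage("segment", segment)

    def embed():
        corpus = TokenizedCorpus([tokens_by_id[r.id] for r in records])
        matrix = train_skipgram(
            corpus,
            dimension=config.embedding_dim,
            context_window=config.context_window,
            negative_samples=config.negative_samples,
            epochs=config.embedding_epochs,
            learning_rate=config.learning_rate,
            random_seed=seeds["embed"],
        )
        path = out / "embeddings.txt"
        write_embeddings(matrix, path)
        artifacts["embeddings"] = path
        return matrix

    matrix = run_stage("embed", embed)

    def vectorize():
        vectors = vectorize_records(tokens_by_id, matrix)
        path = out / "vectors.txt"
        with open(path, "w") as fh:
            for rec in records:
                comps = " ".join(repr(float(v)) for v in vectors[rec.id].values)
                fh.write(f"{rec.id} {comps}\n")
        artifacts["vectors"] = path
        return vectors

    vectors = run_stage("vectorize", vectorize)

    def train():
        split = split_dataset(pairs, fractions=config.split_fractions,
                              seed=seeds["train"])
        model = train_classifier(
            pair_features(split.train, vectors),
            pair_features(split.validation, vectors),
            dropout_rate=config.dropout_rate,
            batch_size=config.batch_size,
            random_seed=seeds["train"],
        )
        path = out / "model.npz"
        save_model(model, path)
        artifacts["model"] = path
        return split, model

    split, model = run_stage("train", train)

    def evaluate():
        probs = predict_pairs(model, pair_features(split.test, vectors,
                                                   labeled=False))
        labels = [p.label for p in split.test]
        calls = (probs >= 0.5).astype(int)
        report = metrics(confusion(labels, calls.tolist()))
        roc_points, auc = roc_auc(probs, labels)
        report.auc = auc
        report.roc_points = roc_points
        metrics_path = out / "metrics.txt"
        with open(metrics_path, "w") as fh:
            for key, value in report.as_dict().items():
                fh.write(f"{key} = {value!r}\n")
        roc_path = out / "roc.tsv"
        with open(roc_path, "w") as fh:
            for fpr, tpr in roc_points:
                fh.write(f"{fpr!r}\t{tpr!r}\n")
        artifacts["metrics"] = metrics_path
        artifacts["roc"] = roc_path
        return report

    report = run_stage("evaluate", evaluate)

    config_path = out / "config.txt"
    write_config(config, config_path)
    artifacts["config"] = config_path

    manifest = {
        "stages": list(STAGES),
        "seeds": seeds,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "metrics": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in report.as_dict().items()},
        "artifacts": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in artifacts.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
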