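"""Readers and writers for on-disk artifacts.

Formats: FASTA protein sequences (via Biopython), tab-separated labeled pair
lists (``id_a<TAB>id_b<TAB>label``), vocabulary tables
(``word<TAB>probability``), embeddings in the word2vec text dialect, and flat
``key = value`` run-configuration files.

Residue policy: sequences are uppercased; the 20 canonical amino acids are
accepted; the ambiguity codes B, Z and U are mapped to D, E and C; X is kept
as a dedicated unknown residue; any other character is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_RESIDUE = "X"
#: B/Z/U are the common ambiguity codes in curated PPI sequence sets.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C"}
ACCEPTED_ALPHABET = frozenset(CANONICAL_AA + UNKNOWN_RESIDUE)


class FormatError(ValueError):
    """Raised for malformed or inconsistent on-disk artifacts."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a whitespace-free unique identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid protein id {self.id!r}: empty or contains whitespace")
        if not self.residues:
            raise FormatError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.residues) - ACCEPTED_ALPHABET
        if bad:
            raise FormatError(
                f"protein {self.id!r} contains unaccepted residue(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class LabeledPair:
    """Two protein ids with a binary interaction label (1 = interacting)."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise FormatError(f"pair ({self.id_a}, {self.id_b}): label must be 0 or 1")


def sanitize_residues(raw: str, *, context: str = "sequence") -> str:
    """Apply the residue policy: uppercase, map B/Z/U, keep X, reject the rest."""
    seq = raw.upper()
    for src, dst in AMBIGUITY_MAP.items():
        seq = seq.replace(src, dst)
    bad = set(seq) - ACCEPTED_ALPHABET
    if bad:
        raise FormatError(f"{context}: unaccepted residue character(s) {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Duplicate ids, empty sequences and characters outside the residue policy
    raise :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        name = entry.id
        if not name:
            raise FormatError(f"{path}: FASTA entry with empty header")
        if name in seen:
            raise FormatError(f"{path}: duplicate sequence id {name!r}")
        seen.add(name)
        raw = str(entry.seq)
        if not raw:
            raise FormatError(f"{path}: sequence {name!r} is empty")
        records.append(ProteinRecord(name, sanitize_residues(raw, context=f"sequence {name!r}")))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def read_pairs(path: str | Path, sequences: Sequence[ProteinRecord]) -> list[LabeledPair]:
    """Read ``id_a<TAB>id_b<TAB>label`` lines, validating ids against *sequences*."""
    known = {rec.id for rec in sequences}
    pairs: list[LabeledPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            id_a, id_b, raw_label = parts
            for pid in (id_a, id_b):
                if pid not in known:
                    raise FormatError(f"{path}:{lineno}: unknown protein id {pid!r}")
            if raw_label not in ("0", "1"):
                raise FormatError(f"{path}:{lineno}: label must be 0 or 1, got {raw_label!r}")
            pairs.append(LabeledPair(id_a, id_b, int(raw_label)))
    return pairs


def write_pairs(pairs: Iterable[LabeledPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")


def write_vocabulary(vocab, path: str | Path) -> None:
    """Write a vocabulary as ``word<TAB>probability``, full float precision."""
    entries = vocab.entries
    if not entries:
        raise FormatError("refusing to write an empty vocabulary")
    with open(path, "w") as fh:
        for word in sorted(entries):
            fh.write(f"{word}\t{entries[word]!r}\n")


def read_vocabulary(path: str | Path):
    from bioword.segmentation import Vocabulary

    entries: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'word<TAB>probability'")
            word, raw_p = parts
            try:
                p = float(raw_p)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric probability {raw_p!r}") from exc
            if word in entries:
                raise FormatError(f"{path}:{lineno}: duplicate word {word!r}")
            entries[word] = p
    return Vocabulary(entries)


def write_embeddings(matrix, path: str | Path) -> None:
    """Write the word (input) vectors in the word2vec text dialect.

    Header line ``W n`` (lexicon size, dimension) followed by one
    ``word v1 ... vn`` line per word.  The output table is training state and
    is not persisted, matching the word2vec convention.
    """
    if len(matrix.words) == 0:
        raise FormatError("refusing to write an empty embedding matrix")
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.words)} {matrix.dimension}\n")
        for word, row in zip(matrix.words, matrix.input_vectors):
            comps = " ".join(repr(float(v)) for v in row)
            fh.write(f"{word} {comps}\n")


def read_embeddings(path: str | Path):
    from bioword.embedding import EmbeddingMatrix

    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: malformed header, expected 'W n'")
        try:
            n_words, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer header fields") from exc
        words: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != dim + 1:
                raise FormatError(f"{path}:{lineno}: expected word + {dim} components")
            words.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric vector component") from exc
    if len(words) != n_words:
        raise FormatError(f"{path}: header declares {n_words} words, found {len(words)}")
    vectors = np.asarray(rows, dtype=np.float64)
    return EmbeddingMatrix(
        words=words,
        input_vectors=vectors,
        output_vectors=np.zeros_like(vectors),
    )


@dataclass
class RunConfig:
    """Pipeline hyperparameters with the defaults used throughout.

    ``alpha_keep_percent`` is the pruning fraction of the vocabulary learner
    (keep the top alpha% of removable words per round, default 70);
    ``dropout_rate`` and ``batch_size`` are classifier training settings
    (defaults 0.5 and 64); ``split_fractions`` is (train, validation, test).
    """

    vocab_size: int = 2000
    seed_vocab_size: int = 8000
    alpha_keep_percent: float = 70.0
    embedding_dim: int = 64
    context_window: int = 5
    negative_samples: int = 5
    embedding_epochs: int = 5
    learning_rate: float = 0.025
    max_word_len: int = 8
    dropout_rate: float = 0.5
    batch_size: int = 64
    random_seed: int = 0
    split_fractions: tuple[float, float, float] = (0.72, 0.18, 0.10)

    def __post_init__(self) -> None:
        for name in ("vocab_size", "seed_vocab_size", "embedding_dim", "context_window",
                     "negative_samples", "embedding_epochs", "batch_size", "max_word_len"):
            if getattr(self, name) < 1:
                raise FormatError(f"RunConfig.{name} must be a positive integer")
        if not (0 < self.alpha_keep_percent <= 100):
            raise FormatError("RunConfig.alpha_keep_percent must lie in (0, 100]")
        if not (0 <= self.dropout_rate < 1):
            raise FormatError("RunConfig.dropout_rate must lie in [0, 1)")
        fr = tuple(float(f) for f in self.split_fractions)
        if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise FormatError("RunConfig.split_fractions must be 3 non-negative numbers summing to 1")
        self.split_fractions = fr


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fields(config):
            value = getattr(config, f.name)
            if isinstance(value, tuple):
                value = ",".join(repr(v) for v in value)
            fh.write(f"{f.name} = {value}\n")


def read_config(path: str | Path) -> RunConfig:
    kwargs: dict = {}
    valid = {f.name: f for f in fields(RunConfig)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in valid:
                raise FormatError(f"{path}:{lineno}: unknown configuration key {key!r}")
            if key == "split_fractions":
                kwargs[key] = tuple(float(x) for x in raw.split(","))
            elif key in ("alpha_keep_percent", "dropout_rate", "learning_rate"):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = int(raw)
    return RunConfig(**kwargs)
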