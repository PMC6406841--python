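"""Confusion-matrix metrics, ROC/AUC and the dataset split protocol.

Metrics follow the standard definitions: accuracy (TP+TN)/total, sensitivity
TP/(TP+FN), precision TP/(TP+FP) and the Matthews correlation coefficient
(TP*TN - FP*FN) / sqrt((TP+FN)(FP+TN)(TP+FP)(FN+TN)).  A metric whose
denominator is zero is reported as NaN together with the reason, never as a
silent zero.  The ROC curve sweeps every score threshold and the AUC is the
trapezoidal integral, which equals the tie-aware normalized Mann-Whitney U
statistic.

The split protocol draws nine tenths of the pairs for model fitting — split
80/20 into training and validation — and holds out the remaining tenth as
the test set, i.e. fractions 0.72/0.18/0.10, stratified by label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

from bioword.io_formats import LabeledPair

__all__ = [
    "ConfusionCounts", "MetricReport", "DataSplit", "EvaluationError",
    "confusion", "metrics", "roc_auc", "split_dataset",
]


class EvaluationError(ValueError):
    """Raised for inconsistent labels, scores or split requests."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Scalar metrics plus optional ROC data.

    ``undefined`` maps a metric name to the reason its denominator vanished;
    such metrics hold NaN.
    """

    accuracy: float
    sensitivity: float
    precision: float
    mcc: float
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out

    def summary(self) -> str:
        lines = []
        for name, value in self.as_dict().items():
            if name in self.undefined:
                lines.append(f"{name}: undefined ({self.undefined[name]})")
            else:
                lines.append(f"{name}: {value:.4f}")
        return "\n".join(lines)


def confusion(labels: Sequence[int], calls: Sequence[int]) -> ConfusionCounts:
    """Tally the 2x2 confusion matrix of binary calls against labels."""
    if len(labels) != len(calls):
        raise EvaluationError(
            f"length mismatch: {len(labels)} labels vs {len(calls)} calls"
        )
    tp = fp = tn = fn = 0
    for y, c in zip(labels, calls):
        if y not in (0, 1) or c not in (0, 1):
            raise EvaluationError("labels and calls must be binary")
        if y == 1:
            if c == 1:
                tp += 1
            else:
                fn += 1
        else:
            if c == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, precision and MCC from confusion counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    undefined: dict[str, str] = {}

    def ratio(name: str, num: float, den: float) -> float:
        if den == 0:
            undefined[name] = "zero denominator"
            return math.nan
        return num / den

    accuracy = ratio("accuracy", tn + tp, counts.total)
    sensitivity = ratio("sensitivity", tp, tp + fn)
    precision = ratio("precision", tp, tp + fp)
    mcc_den = math.sqrt(
        float(fn + tp) * float(fp + tn) * float(fp + tp) * float(fn + tn)
    )
    if mcc_den == 0:
        undefined["mcc"] = "a confusion-matrix margin is zero"
        mcc = math.nan
    else:
        mcc = ((tn * tp) - (fn * fp)) / mcc_den
    return MetricReport(
        accuracy=accuracy, sensitivity=sensitivity,
        precision=precision, mcc=mcc, undefined=undefined,
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) over all thresholds and the trapezoidal AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise EvaluationError("scores and labels must have equal length")
    classes = set(np.unique(labels).tolist())
    if not classes <= {0, 1}:
        raise EvaluationError("labels must be binary")
    if classes != {0, 1}:
        raise EvaluationError("ROC requires both classes to be present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass(frozen=True)
class DataSplit:
    train: list[LabeledPair]
    validation: list[LabeledPair]
    test: list[LabeledPair]
    seed: int


def split_dataset(
    pairs: Sequence[LabeledPair],
    fractions: tuple[float, float, float] = (0.72, 0.18, 0.10),
    seed: int = 0,
) -> DataSplit:
    """Stratified train/validation/test partition, reproducible under *seed*.

    Within each label stratum the pairs are shuffled and allocated by
    largest-remainder rounding, so realized counts are within one pair of
    the configured fractions per stratum and the three parts partition the
    input exactly.
    """
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
        raise EvaluationError("fractions must be 3 non-negative numbers summing to 1")
    if not pairs:
        raise EvaluationError("cannot split an empty pair collection")
    strata: dict[int, list[LabeledPair]] = {0: [], 1: []}
    for p in pairs:
        strata[p.label].append(p)
    for label, members in strata.items():
        if not members:
            raise EvaluationError(f"label stratum {label} is empty")
    rng = np.random.default_rng(seed)
    parts: tuple[list[LabeledPair], ...] = ([], [], [])
    for label in (0, 1):
        members = strata[label]
        order = rng.permutation(len(members))
        n = len(members)
        exact = [f * n for f in fr]
        counts = [int(math.floor(e)) for e in exact]
        remainders = sorted(
            range(3), key=lambda i: (exact[i] - counts[i], i), reverse=True
        )
        short = n - sum(counts)
        for i in range(short):
            counts[remainders[i]] += 1
        start = 0
        for part, count in zip(parts, counts):
            part.extend(members[i] for i in order[start : start + count])
            start += count
    return DataSplit(train=parts[0], validation=parts[1], test=parts[2], seed=seed)
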