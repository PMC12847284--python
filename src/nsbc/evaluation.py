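"""Validation protocol: stratified k-fold CV, confusion matrices, balanced accuracy.

Balanced accuracy (BA) is the unweighted mean of per-class sensitivities
(macro recall); on two classes it reduces to (sensitivity + specificity)/2.
It is the headline metric here because the clinical tables this classifier
targets are class-imbalanced, where plain accuracy rewards predicting the
majority class.  The imbalance ratio IR = majority count / minority count
(>= 1) summarises how skewed a dataset is.

Cross-validation refits the preprocessor, the bit widths and the memory on
each training fold only, so fold metrics are leakage-free by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seeds import stream
from .classifier import NSBCModel, fit_nsbc
from .preprocessing import RawTable
from .rbc import GRAY

__all__ = [
    "ConfusionMatrix",
    "FoldAssignment",
    "MetricReport",
    "stratified_kfold",
    "confusion",
    "per_class_sensitivity",
    "balanced_accuracy",
    "imbalance_ratio",
    "run_cv",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """c x c counts; rows are true classes, columns predicted, in class order."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square with one row per class")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def sensitivity(self) -> float:
        """Binary only: recall of the positive (second) class... see note.

        By the usual clinical convention the first class in sorted order is
        taken as positive here; for symmetric reporting use
        :func:`per_class_sensitivity`.
        """
        self._require_binary()
        tp, fn = self.counts[0, 0], self.counts[0, 1]
        return float(tp) / float(tp + fn)

    def specificity(self) -> float:
        self._require_binary()
        tn, fp = self.counts[1, 1], self.counts[1, 0]
        return float(tn) / float(tn + fp)

    def _require_binary(self) -> None:
        if len(self.classes) != 2:
            raise ValueError("sensitivity/specificity as scalars need a binary problem")


@dataclass
class FoldAssignment:
    """Fold index (0..k-1) per instance; partitions the index set."""

    fold: np.ndarray
    k: int
    seed: int

    def test_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold == f)

    def train_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold != f)


@dataclass
class MetricReport:
    """Per-fold and aggregate CV metrics."""

    fold_ba: list[float]
    mean_ba: float
    pooled: ConfusionMatrix
    ir: float
    n: int
    k: int
    seed: int
    fold_bits: list[int] = field(default_factory=list)  # encoded length per training fold

    def binary_summary(self) -> dict[str, float] | None:
        if len(self.pooled.classes) != 2:
            return None
        return {
            "sensitivity": self.pooled.sensitivity(),
            "specificity": self.pooled.specificity(),
            "accuracy": self.pooled.accuracy(),
            "balanced_accuracy": balanced_accuracy(self.pooled),
        }


def stratified_kfold(labels: Sequence[object], k: int, seed: int) -> FoldAssignment:
    """Shuffle within each class with a seeded RNG, then deal round-robin to folds.

    Per-class fold counts differ by at most one, so fold class proportions
    track the full table's.  If k exceeds the smallest class count a warning
    is logged (some folds will lack that class) but the split proceeds.
    """
    toks = np.asarray([str(t) for t in labels], dtype=object)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(toks, return_counts=True)
    if counts.min() < 1:
        raise ValueError("every class needs at least one instance")
    if k > counts.min():
        logger.warning(
            "k=%d exceeds smallest class count %d; some folds will miss class %r",
            k, int(counts.min()), str(classes[int(counts.argmin())]),
        )
    rng = stream(seed, "cv-shuffle")
    fold = np.empty(len(toks), dtype=np.int64)
    for c in classes:
        pos = np.flatnonzero(toks == c)
        pos = pos[rng.permutation(len(pos))]
        fold[pos] = np.arange(len(pos)) % k
    return FoldAssignment(fold=fold, k=k, seed=seed)


def confusion(
    true_labels: Sequence[object],
    predicted_labels: Sequence[object],
    classes: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """counts[i, j] = number of instances of true class i predicted as class j."""
    t = [str(x) for x in true_labels]
    p = [str(x) for x in predicted_labels]
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences differ in length")
    if classes is None:
        cls = tuple(sorted(set(t) | set(p)))
    else:
        cls = tuple(classes)
        unseen = (set(t) | set(p)) - set(cls)
        if unseen:
            raise ValueError(f"labels {sorted(unseen)} not in the declared class set")
    idx = {c: i for i, c in enumerate(cls)}
    counts = np.zeros((len(cls), len(cls)), dtype=np.int64)
    for a, b in zip(t, p):
        counts[idx[a], idx[b]] += 1
    return ConfusionMatrix(counts=counts, classes=cls)


def per_class_sensitivity(cm: ConfusionMatrix) -> np.ndarray:
    """diagonal_i / row-sum_i per class; NaN (with a warning) for empty rows."""
    rows = cm.counts.sum(axis=1)
    out = np.full(len(cm.classes), np.nan)
    for i, n_i in enumerate(rows):
        if n_i == 0:
            logger.warning("class %r has no instances; excluded from BA", cm.classes[i])
        else:
            out[i] = cm.counts[i, i] / n_i
    return out


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class sensitivities over represented classes."""
    sens = per_class_sensitivity(cm)
    if np.isnan(sens).all():
        raise ValueError("no represented class; balanced accuracy undefined")
    return float(np.nanmean(sens))


def imbalance_ratio(labels: Sequence[object]) -> float:
    """Majority class count divided by minority class count (>= 1)."""
    toks = [str(t) for t in labels]
    _, counts = np.unique(np.asarray(toks, dtype=object), return_counts=True)
    if len(counts) < 2:
        raise ValueError("imbalance ratio needs at least two classes")
    return float(counts.max()) / float(counts.min())


def run_cv(
    table: RawTable,
    n: int,
    k: int = 10,
    seed: int = 1,
    encoding: str = GRAY,
) -> MetricReport:
    """Stratified k-fold CV of the full n-SBC pipeline.

    Preprocessing, bit widths and the memory matrix are fitted on each
    training fold alone.  Fold BA is computed over the classes represented
    in that test fold; the pooled confusion matrix across folds is also
    reported.
    """
    labels = table.labels.to_numpy(dtype=object)
    classes = tuple(sorted({str(t) for t in labels}))
    folds = stratified_kfold(labels, k=k, seed=seed)
    fold_ba: list[float] = []
    fold_bits: list[int] = []
    pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for f in range(k):
        test_idx = folds.test_indices(f)
        if len(test_idx) == 0:
            logger.warning("fold %d is empty; skipped", f)
            continue
        model = fit_nsbc(table.take(folds.train_indices(f)), n=n, encoding=encoding)
        fold_bits.append(model.profile.total_bits)
        test = table.take(test_idx)
        pred = model.predict_table(test)
        cm = confusion(test.labels, pred, classes=classes)
        pooled += cm.counts
        fold_ba.append(balanced_accuracy(cm))
    return MetricReport(
        fold_ba=fold_ba,
        mean_ba=float(np.mean(fold_ba)),
        pooled=ConfusionMatrix(counts=pooled, classes=classes),
        ir=imbalance_ratio(labels),
        n=n,
        k=k,
        seed=seed,
        fold_bits=fold_bits,
    )
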