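"""The n-SBC core: memory of encoded training patterns and top-n Hamming scoring.

Learning stores every Gray-encoded training bit string verbatim in a memory
matrix M with its class label.  To classify a query b (u bits), the model
computes a similarity z = u - H(b, b_mu) for every stored pattern, sums the
n largest z within each class, and predicts the class with the maximal sum
(ties break to the lowest class index; the full one-hot indicator is exposed
so callers can see ties).  Aggregating only the n best matches per class
caps the evidence a large class can accumulate, which is what makes the rule
robust to class imbalance.

Because similarity is counted per bit and bits belong to feature segments,
every decision decomposes into per-training-pattern, per-feature matched-bit
counts — the explanation report.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocessing import PreprocessModel, RawTable, fit_preprocessor, transform
from .rbc import (
    GRAY,
    EncodedPattern,
    WidthProfile,
    bits_to_str,
    encode_matrix,
    fit_widths,
    str_to_bits,
)

__all__ = [
    "MemoryMatrix",
    "SimilarityVector",
    "ClassScoreVector",
    "Explanation",
    "NSBCModel",
    "hamming",
    "fit",
    "similarity_vector",
    "class_scores",
    "decide",
    "predict",
    "explain",
    "fit_nsbc",
    "PRESETS",
]

logger = logging.getLogger(__name__)

#: The two shipped classifier variants: top-3 and top-5 aggregation.
PRESETS: dict[str, int] = {"3-SBC": 3, "5-SBC": 5}


def _as_bits(x) -> np.ndarray:
    if isinstance(x, EncodedPattern):
        return x.bits
    if isinstance(x, str):
        return str_to_bits(x)
    return np.asarray(x, dtype=np.uint8)


def hamming(a, b) -> int:
    """Number of positions at which two equal-length bit strings differ."""
    av, bv = _as_bits(a), _as_bits(b)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape} vs {bv.shape}")
    return int(np.count_nonzero(av != bv))


@dataclass
class MemoryMatrix:
    """The learned model: stored training bit strings with class labels."""

    bits: np.ndarray  # (m, u) uint8
    labels: np.ndarray  # (m,) int class codes
    class_names: tuple[str, ...]
    profile: WidthProfile | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def u(self) -> int:
        return self.bits.shape[1]

    @property
    def n_patterns(self) -> int:
        return self.bits.shape[0]

    @property
    def class_counts(self) -> tuple[int, ...]:
        return tuple(int((self.labels == i).sum()) for i in range(len(self.class_names)))

    @property
    def k_min(self) -> int:
        return min(self.class_counts)

    def class_positions(self, class_idx: int) -> np.ndarray:
        return np.flatnonzero(self.labels == class_idx)


@dataclass
class SimilarityVector:
    """Per-training-pattern similarity z = u - Hamming(query, pattern)."""

    z: np.ndarray  # (m,) int
    query_bits: np.ndarray  # (u,) uint8


@dataclass
class ClassScoreVector:
    """Top-n aggregated score per class, its one-hot decision, and the picks."""

    n_used: tuple[int, ...]
    scores: tuple[int, ...]
    selected: tuple[np.ndarray, ...]  # training-pattern indices behind each score
    onehot: tuple[int, ...]
    predicted: int  # class index


@dataclass
class ExplainedPattern:
    """One selected training pattern and how its bits matched the query."""

    index: int
    class_name: str
    bits: str
    match_vector: str  # 1 where the stored bit equals the query bit
    z: int
    segment_matches: tuple[int, ...]  # matched bits per feature segment


@dataclass
class Explanation:
    """Which stored patterns, and which features of them, drove a decision."""

    query_bits: str
    per_class: dict[str, list[ExplainedPattern]]
    scores: dict[str, int]
    predicted: str
    margin: int  # best score minus runner-up

    def render(self) -> str:
        lines = [
            f"query bits : {self.query_bits}",
            f"predicted  : {self.predicted}  (margin {self.margin})",
            "",
            f"{'pattern':>8} {'class':>6} {'stored bits':>14} {'match vector':>14} {'z':>4}  per-feature matches",
        ]
        for cname, entries in self.per_class.items():
            for e in entries:
                seg = "+".join(str(s) for s in e.segment_matches)
                lines.append(
                    f"{'b' + str(e.index + 1):>8} {cname:>6} {e.bits:>14} "
                    f"{e.match_vector:>14} {e.z:>4}  {seg}"
                )
        lines.append("")
        lines.append(
            "class scores: "
            + ", ".join(f"{c}={s}" for c, s in self.scores.items())
        )
        return "\n".join(lines)


def fit(encoded_patterns, labels: Sequence[object], profile: WidthProfile | None = None) -> MemoryMatrix:
    """Store every training pattern verbatim with its label.

    ``encoded_patterns`` may be a 2-D 0/1 array, a sequence of
    :class:`EncodedPattern`, or a sequence of '0'/'1' strings.  Class codes
    are assigned in sorted token order.  Requires >= 2 classes, each with at
    least one pattern, all patterns the same length.
    """
    if isinstance(encoded_patterns, np.ndarray) and encoded_patterns.ndim == 2:
        bits = encoded_patterns.astype(np.uint8)
    else:
        rows = [_as_bits(p) for p in encoded_patterns]
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent pattern lengths: {sorted(lengths)}")
        bits = np.vstack(rows).astype(np.uint8) if rows else np.empty((0, 0), np.uint8)
        if profile is None and encoded_patterns and isinstance(encoded_patterns[0], EncodedPattern):
            profile = encoded_patterns[0].profile
    toks = [str(t) for t in labels]
    if bits.shape[0] != len(toks):
        raise ValueError("number of patterns and labels differ")
    if bits.shape[0] == 0:
        raise ValueError("cannot fit on an empty training set")
    class_names = tuple(sorted(set(toks)))
    if len(class_names) < 2:
        raise ValueError("need at least two classes in the training set")
    code = {c: i for i, c in enumerate(class_names)}
    lab = np.array([code[t] for t in toks], dtype=np.int64)
    return MemoryMatrix(bits=bits, labels=lab, class_names=class_names, profile=profile)


def similarity_vector(memory: MemoryMatrix, query) -> SimilarityVector:
    """z_mu = u - Hamming(query, pattern_mu), in stored pattern order."""
    q = _as_bits(query)
    if len(q) != memory.u:
        raise ValueError(f"query length {len(q)} != memory pattern length {memory.u}")
    h = np.count_nonzero(memory.bits != q[np.newaxis, :], axis=1)
    return SimilarityVector(z=(memory.u - h).astype(np.int64), query_bits=q)


def class_scores(zv: SimilarityVector, memory: MemoryMatrix, n: int) -> ClassScoreVector:
    """Sum the n largest similarities within each class.

    n clamps to the class size when a class holds fewer than n patterns
    (logged as a warning).  Selected indices are recorded for explanation;
    ties among equal z break toward the lowest pattern index.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    n_used, scores, selected = [], [], []
    for i in range(len(memory.class_names)):
        pos = memory.class_positions(i)
        k_i = len(pos)
        m = min(n, k_i)
        if m < n:
            logger.warning(
                "n=%d exceeds class %r size %d; clamping to %d",
                n, memory.class_names[i], k_i, m,
            )
        order = np.argsort(-zv.z[pos], kind="stable")
        sel = pos[order[:m]]
        n_used.append(m)
        scores.append(int(zv.z[sel].sum()))
        selected.append(sel)
    predicted, onehot = decide(scores)
    return ClassScoreVector(
        n_used=tuple(n_used),
        scores=tuple(scores),
        selected=tuple(selected),
        onehot=onehot,
        predicted=predicted,
    )


def decide(scores) -> tuple[int, tuple[int, ...]]:
    """One-hot mark every class attaining the maximal score; predict the lowest index."""
    vals = [int(s) for s in (scores.scores if isinstance(scores, ClassScoreVector) else scores)]
    if not vals:
        raise ValueError("no class scores to decide over")
    best = max(vals)
    onehot = tuple(1 if v == best else 0 for v in vals)
    return onehot.index(1), onehot


def predict(
    memory: MemoryMatrix,
    raw_query: RawTable,
    preprocess_model: PreprocessModel,
    profile: WidthProfile,
    n: int,
    encoding: str = GRAY,
) -> np.ndarray:
    """End-to-end labels for a raw table: encode, score, decide per row."""
    x, _ = transform(raw_query, preprocess_model)
    bits = encode_matrix(x, profile, encoding=encoding)
    out = []
    for row in bits:
        sv = similarity_vector(memory, row)
        cs = class_scores(sv, memory, n)
        out.append(memory.class_names[cs.predicted])
    return np.asarray(out, dtype=object)


def explain(memory: MemoryMatrix, query, n: int) -> Explanation:
    """Report the top-n patterns per class and their per-feature matched bits."""
    if memory.profile is None:
        raise ValueError("memory has no width profile; cannot attribute bits to features")
    sv = similarity_vector(memory, query)
    cs = class_scores(sv, memory, n)
    per_class: dict[str, list[ExplainedPattern]] = {}
    for i, cname in enumerate(memory.class_names):
        entries = []
        for idx in cs.selected[i]:
            stored = memory.bits[int(idx)]
            match = (stored == sv.query_bits).astype(np.uint8)
            seg = tuple(
                int(match[a:b].sum()) for a, b in memory.profile.segments
            )
            entries.append(
                ExplainedPattern(
                    index=int(idx),
                    class_name=cname,
                    bits=bits_to_str(stored),
                    match_vector=bits_to_str(match),
                    z=int(sv.z[idx]),
                    segment_matches=seg,
                )
            )
        per_class[cname] = entries
    ordered = sorted(cs.scores, reverse=True)
    margin = ordered[0] - (ordered[1] if len(ordered) > 1 else 0)
    return Explanation(
        query_bits=bits_to_str(sv.query_bits),
        per_class=per_class,
        scores={c: s for c, s in zip(memory.class_names, cs.scores)},
        predicted=memory.class_names[cs.predicted],
        margin=margin,
    )


@dataclass
class NSBCModel:
    """A fitted n-SBC pipeline: preprocessor + width profile + memory + n."""

    preprocess: PreprocessModel
    profile: WidthProfile
    memory: MemoryMatrix
    n: int
    encoding: str = GRAY

    def predict_table(self, table: RawTable) -> np.ndarray:
        return predict(self.memory, table, self.preprocess, self.profile, self.n, self.encoding)

    def explain_row(self, table: RawTable, row: int) -> Explanation:
        x, _ = transform(table.take([row]), self.preprocess)
        bits = encode_matrix(x, self.profile, encoding=self.encoding)[0]
        return explain(self.memory, bits, self.n)

    # --- persistence: one JSON file, bit-exact round trip ---

    def to_dict(self) -> dict:
        return {
            "format": "nsbc-model",
            "version": 1,
            "n": self.n,
            "encoding": self.encoding,
            "preprocess": self.preprocess.to_dict(),
            "profile": self.profile.to_dict(),
            "memory": {
                "patterns": [bits_to_str(b) for b in self.memory.bits],
                "labels": [self.memory.class_names[i] for i in self.memory.labels],
                "class_names": list(self.memory.class_names),
            },
        }

    def save(self, path: str) -> None:
        text = json.dumps(self.to_dict(), indent=1)
        d = os.path.dirname(os.path.abspath(path))
        fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(text)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    @classmethod
    def from_dict(cls, d: dict) -> "NSBCModel":
        profile = WidthProfile.from_dict(d["profile"])
        mem = d["memory"]
        memory = fit(mem["patterns"], mem["labels"], profile=profile)
        if tuple(mem["class_names"]) != memory.class_names:
            raise ValueError("stored class names are not in sorted order")
        return cls(
            preprocess=PreprocessModel.from_dict(d["preprocess"]),
            profile=profile,
            memory=memory,
            n=int(d["n"]),
            encoding=d.get("encoding", GRAY),
        )

    @classmethod
    def load(cls, path: str) -> "NSBCModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_nsbc(train: RawTable, n: int, encoding: str = GRAY) -> NSBCModel:
    """Fit the full pipeline on a raw training table."""
    pre = fit_preprocessor(train)
    x, y = transform(train, pre)
    profile = fit_widths(x)
    bits = encode_matrix(x, profile, encoding=encoding)
    memory = fit(bits, y, profile=profile)
    return NSBCModel(preprocess=pre, profile=profile, memory=memory, n=n, encoding=encoding)
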