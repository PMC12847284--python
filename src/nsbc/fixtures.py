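"""The six-bit, five-pattern teaching example of the classifier's operation.

Two features and five training rows: x1, x2 in class A; x3, x4, x5 in
class B.  The published bit strings for these rows are injected directly
as the encoded memory (the raw values are retained for reference only —
they do not determine the bit strings through the standard preprocessing
path, whose behaviour is validated separately against the encoder's own
conversion tables).  The fixture also carries the intermediate quantities
the classification of query 110010 with n = 2 must produce, so tests can
check every stage of the pipeline against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import MemoryMatrix, fit
from .rbc import WidthProfile

__all__ = ["WorkedExampleFixture", "make_worked_example"]


@dataclass
class WorkedExampleFixture:
    raw_patterns: tuple[tuple[float, float], ...]
    encoded: tuple[str, ...]
    labels: tuple[str, ...]
    query_raw: tuple[float, float]
    query_bits: str
    n: int
    # intermediates the classifier must reproduce
    expected_z: tuple[int, ...]
    expected_scores: dict[str, int]
    expected_onehot: tuple[int, ...]
    expected_class: str
    expected_match_vectors: tuple[str, ...]  # 1 where stored bit equals query bit

    @property
    def profile(self) -> WidthProfile:
        # two features, three bits each
        return WidthProfile.from_widths((3, 3))

    def memory(self) -> MemoryMatrix:
        return fit(list(self.encoded), list(self.labels), profile=self.profile)


def make_worked_example() -> WorkedExampleFixture:
    """The five-pattern fixture with its expected intermediates."""
    return WorkedExampleFixture(
        raw_patterns=(
            (0.28, 0.17),
            (0.21, 0.09),
            (0.06, -0.15),
            (-0.24, 0.01),
            (0.07, -0.28),
        ),
        encoded=("101111", "111110", "010001", "000010", "110000"),
        labels=("A", "A", "B", "B", "B"),
        query_raw=(0.16, 0.05),
        query_bits="110010",
        n=2,
        expected_z=(2, 4, 3, 4, 5),
        expected_scores={"A": 6, "B": 9},
        expected_onehot=(0, 1),
        expected_class="B",
        expected_match_vectors=("100010", "110011", "011100", "001111", "111101"),
    )
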