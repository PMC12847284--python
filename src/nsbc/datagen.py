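"""Synthetic imbalanced clinical-style tables.

The generator emulates the data regime the classifier targets: small tables
(tens to low thousands of rows), 2-6 classes, imbalance ratios from 1 up to
about 31, a mix of numeric and categorical features, and a sprinkling of
missing cells.  Numeric features are Gaussian clusters whose class centers
sit ``class_sep`` apart; categorical features favour one class-specific
level with probability ``level_affinity``.  Class counts follow the
requested proportions by largest-remainder allocation, so the realised
imbalance ratio matches the request up to rounding.

Everything is deterministic under the seed: the same SynthSpec always
yields the same table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import stream
from .preprocessing import RawTable

__all__ = ["SynthSpec", "proportions_from_ir", "allocate_counts", "generate"]


def proportions_from_ir(ir: float, n_classes: int = 2) -> tuple[float, ...]:
    """Class proportions whose majority/minority ratio equals ``ir``.

    Class weights interpolate linearly from ``ir`` (class 0, majority) down
    to 1 (last class, minority), then normalise; with two classes this is
    exactly (ir, 1) / (ir + 1).
    """
    if ir < 1:
        raise ValueError("imbalance ratio must be >= 1")
    if n_classes < 2:
        raise ValueError("need at least two classes")
    weights = np.linspace(ir, 1.0, n_classes)
    return tuple(weights / weights.sum())


def allocate_counts(n: int, proportions) -> tuple[int, ...]:
    """Largest-remainder allocation of n samples to the given proportions."""
    p = np.asarray(proportions, dtype=float)
    if p.min() <= 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be positive and sum to 1")
    base = np.floor(p * n).astype(int)
    frac = p * n - base
    # ties on the fractional part resolve to the lower class index
    for i in np.lexsort((np.arange(len(p)), -frac))[: n - base.sum()]:
        base[i] += 1
    if base.min() < 1:
        raise ValueError("a class received zero samples; increase n or rebalance")
    return tuple(int(c) for c in base)


@dataclass
class SynthSpec:
    """Recipe for one synthetic table.

    Defaults describe a typical small clinical screening table: a few
    hundred rows, moderate imbalance, mostly numeric features with a couple
    of categorical ones, and a few percent of cells missing.
    """

    n_samples: int = 300
    n_numeric: int = 4
    n_categorical: int = 2
    n_classes: int = 2
    proportions: tuple[float, ...] | None = None  # derived from ir when None
    ir: float = 3.0
    class_sep: float = 1.0  # distance between adjacent class centers, in noise SDs
    spread: float = 1.0  # Gaussian noise SD of numeric features
    n_levels: int = 3  # levels per categorical feature
    level_affinity: float = 0.7  # probability of a class's preferred level
    missing_rate: float = 0.0
    seed: int = 0

    def resolved_proportions(self) -> tuple[float, ...]:
        if self.proportions is not None:
            p = tuple(float(x) for x in self.proportions)
            if len(p) != self.n_classes:
                raise ValueError("proportions length must equal n_classes")
            return p
        return proportions_from_ir(self.ir, self.n_classes)

    def validate(self) -> None:
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")
        if self.n_numeric + self.n_categorical < 1:
            raise ValueError("need at least one feature")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_levels < 2:
            raise ValueError("categorical features need at least two levels")
        if not (0.0 < self.level_affinity <= 1.0):
            raise ValueError("level_affinity must be in (0, 1]")


def generate(spec: SynthSpec) -> RawTable:
    """Draw one table according to the spec.  Deterministic under spec.seed."""
    spec.validate()
    counts = allocate_counts(spec.n_samples, spec.resolved_proportions())
    rng = stream(spec.seed, "datagen")
    y = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    n = len(y)

    columns: dict[str, np.ndarray] = {}
    for j in range(spec.n_numeric):
        centers = np.array([c * spec.class_sep * spec.spread for c in range(spec.n_classes)])
        columns[f"num{j}"] = rng.normal(centers[y], spec.spread).round(4)
    levels = [f"L{v}" for v in range(spec.n_levels)]
    for j in range(spec.n_categorical):
        vals = np.empty(n, dtype=object)
        for c in range(spec.n_classes):
            pref = (c + j) % spec.n_levels
            w = np.full(spec.n_levels, (1.0 - spec.level_affinity) / (spec.n_levels - 1))
            w[pref] = spec.level_affinity
            mask = y == c
            vals[mask] = rng.choice(levels, size=int(mask.sum()), p=w)
        columns[f"cat{j}"] = vals

    frame = pd.DataFrame(columns).astype(object)
    if spec.missing_rate > 0:
        mask = rng.random(frame.shape) < spec.missing_rate
        frame = frame.mask(pd.DataFrame(mask, columns=frame.columns), other=None)

    labels = pd.Series([f"C{c}" for c in y], name="class")
    # a seeded row shuffle so classes are not block-ordered
    order = rng.permutation(n)
    return RawTable(
        features=frame.iloc[order].reset_index(drop=True),
        labels=labels.iloc[order].reset_index(drop=True),
    )
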