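"""Named seed streams.

One user-facing integer seed fans out into independent RNG streams, one per
stochastic component ("cv-shuffle", "datagen", ...).  Each stream's state
depends only on (seed, name), so adding a new component never perturbs the
draws of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(seed: int, name: str) -> int:
    """A deterministic 31-bit child seed for a named component."""
    h = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def stream(seed: int, name: str) -> np.random.Generator:
    """An independent Generator for the named component under this seed."""
    return np.random.default_rng(child_seed(seed, name))
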