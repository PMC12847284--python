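"""Reflected-binary (Gray) codec with per-feature fixed bit widths.

Gray code maps an integer v to v XOR (v >> 1); consecutive integers then
differ in exactly one bit, so small numeric changes stay small in Hamming
space.  Each feature gets its own fixed width — the bit length of the
training maximum — and a pattern is the concatenation of the per-feature
codes, most significant bit first.  The segment layout is recorded so bits
can be attributed back to features when explaining a decision.

A plain binary (non-reflected) variant is available through the
``encoding="binary"`` switch as an ablation of the Gray step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WidthProfile",
    "EncodedPattern",
    "to_gray",
    "from_gray",
    "fit_widths",
    "encode_pattern",
    "encode_matrix",
    "decode_pattern",
    "bits_to_str",
    "str_to_bits",
]

GRAY = "gray"
BINARY = "binary"


def to_gray(v: int) -> int:
    """Gray-code an integer: v XOR (v >> 1).  The MSB is preserved."""
    v = int(v)
    if v < 0:
        raise ValueError("Gray code is defined for nonnegative integers only")
    return v ^ (v >> 1)


def from_gray(g: int) -> int:
    """Invert :func:`to_gray` by prefix-XOR decoding."""
    g = int(g)
    if g < 0:
        raise ValueError("Gray code is defined for nonnegative integers only")
    v = g
    shift = g >> 1
    while shift:
        v ^= shift
        shift >>= 1
    return v


@dataclass(frozen=True)
class WidthProfile:
    """Per-feature bit widths and their segment layout in the concatenated string."""

    widths: tuple[int, ...]
    segments: tuple[tuple[int, int], ...]  # half-open [start, stop) per feature
    total_bits: int

    @classmethod
    def from_widths(cls, widths) -> "WidthProfile":
        ws = tuple(int(w) for w in widths)
        if not ws or any(w < 1 for w in ws):
            raise ValueError("every feature width must be >= 1")
        segs = []
        start = 0
        for w in ws:
            segs.append((start, start + w))
            start += w
        return cls(widths=ws, segments=tuple(segs), total_bits=start)

    def to_dict(self) -> dict:
        return {"widths": list(self.widths)}

    @classmethod
    def from_dict(cls, d: dict) -> "WidthProfile":
        return cls.from_widths(d["widths"])


@dataclass(frozen=True)
class EncodedPattern:
    """A concatenated bit string with the profile that laid it out."""

    bits: np.ndarray  # uint8 0/1, MSB-first per segment
    profile: WidthProfile

    def __post_init__(self) -> None:
        if len(self.bits) != self.profile.total_bits:
            raise ValueError(
                f"pattern length {len(self.bits)} != profile total_bits "
                f"{self.profile.total_bits}"
            )

    def __len__(self) -> int:
        return len(self.bits)

    def __str__(self) -> str:
        return bits_to_str(self.bits)


def fit_widths(int_matrix) -> WidthProfile:
    """Width per column = max(1, bit length of the column maximum)."""
    m = np.asarray(int_matrix, dtype=np.int64)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("need a nonempty 2-D integer matrix")
    if (m < 0).any():
        raise ValueError("matrix must be nonnegative")
    widths = [max(1, int(m[:, j].max()).bit_length()) for j in range(m.shape[1])]
    return WidthProfile.from_widths(widths)


def _value_bits(v: int, width: int) -> np.ndarray:
    return np.array([(v >> (width - 1 - k)) & 1 for k in range(width)], dtype=np.uint8)


def encode_pattern(int_row, profile: WidthProfile, encoding: str = GRAY) -> EncodedPattern:
    """Encode one integer row: per-feature (Gray) code, left-padded to w_i bits, concatenated."""
    row = [int(v) for v in int_row]
    if len(row) != len(profile.widths):
        raise ValueError(f"row has {len(row)} values, profile expects {len(profile.widths)}")
    chunks = []
    for v, w in zip(row, profile.widths):
        if v < 0 or v >= (1 << w):
            raise ValueError(f"value {v} not representable in {w} bits")
        g = to_gray(v) if encoding == GRAY else v
        chunks.append(_value_bits(g, w))
    return EncodedPattern(bits=np.concatenate(chunks), profile=profile)


def encode_matrix(int_matrix, profile: WidthProfile, encoding: str = GRAY) -> np.ndarray:
    """Vectorised :func:`encode_pattern` over rows; returns an (m, total_bits) uint8 array."""
    m = np.asarray(int_matrix, dtype=np.int64)
    if m.ndim != 2:
        raise ValueError("need a 2-D integer matrix")
    if m.shape[1] != len(profile.widths):
        raise ValueError(
            f"matrix has {m.shape[1]} columns, profile expects {len(profile.widths)}"
        )
    out = np.empty((m.shape[0], profile.total_bits), dtype=np.uint8)
    for j, (w, (start, stop)) in enumerate(zip(profile.widths, profile.segments)):
        col = m[:, j]
        if (col < 0).any() or (col >= (1 << w)).any():
            bad = col[(col < 0) | (col >= (1 << w))][0]
            raise ValueError(f"value {int(bad)} in column {j} not representable in {w} bits")
        g = (col ^ (col >> 1)) if encoding == GRAY else col
        for k in range(w):
            out[:, start + k] = (g >> (w - 1 - k)) & 1
    return out


def decode_pattern(pattern, profile: WidthProfile, encoding: str = GRAY) -> np.ndarray:
    """Recover the integer row from a concatenated bit string (for round-trip checks)."""
    bits = pattern.bits if isinstance(pattern, EncodedPattern) else np.asarray(pattern, dtype=np.uint8)
    if len(bits) != profile.total_bits:
        raise ValueError("bit string length does not match profile")
    vals = []
    for (start, stop) in profile.segments:
        g = 0
        for b in bits[start:stop]:
            g = (g << 1) | int(b)
        vals.append(from_gray(g) if encoding == GRAY else g)
    return np.asarray(vals, dtype=np.int64)


def bits_to_str(bits) -> str:
    return "".join("1" if int(b) else "0" for b in bits)


def str_to_bits(s: str) -> np.ndarray:
    if not s or any(ch not in "01" for ch in s):
        raise ValueError("bit string must be a nonempty sequence of 0/1 characters")
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8) - ord("0")
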