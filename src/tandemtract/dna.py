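"""Core DNA helpers: validation, integer encoding, categories.

All sequences handled by this package are plain uppercase strings over
``{A, C, G, T}``. Alignment kernels work on ``uint8`` code arrays
(A=0, C=1, G=2, T=3) produced by :func:`encode`.
"""

from __future__ import annotations

import enum

import numpy as np

ALPHABET = "ACGT"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


class DnaError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


class Category(enum.Enum):
    """Classification of a motif block within a repeat tract."""

    CANONICAL = "canonical"
    INTERRUPTION = "interruption"
    MISCELLANEOUS = "miscellaneous"


def validate_dna(seq: str, *, allow_empty: bool = False, name: str = "sequence") -> str:
    """Return ``seq`` uppercased, raising :class:`DnaError` on invalid input."""
    if not isinstance(seq, str):
        raise DnaError(f"{name} must be a string, got {type(seq).__name__}")
    seq = seq.upper()
    if not seq:
        if allow_empty:
            return seq
        raise DnaError(f"{name} must be non-empty")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise DnaError(f"{name} contains non-ACGT characters: {sorted(bad)!r}")
    return seq


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a ``uint8`` array (A=0, C=1, G=2, T=3)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max(initial=0) > 3:
        raise DnaError("sequence contains non-ACGT characters")
    return arr


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of the given length."""
    if length < 0:
        raise ValueError("length must be non-negative")
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))
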