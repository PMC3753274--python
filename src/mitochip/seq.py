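"""Nucleotide sequences as numpy code arrays.

Sequences are held as uint8 arrays with A=0, C=1, G=2, T=3. All heavy
operations (k-mer hashing, read extraction, reverse complement) run
vectorised on these arrays; strings appear only at file boundaries.
"""
from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string to a uint8 code array (case-insensitive)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.size and codes.max() > 3:
        bad = chr(raw[int(np.argmax(codes > 3))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _CHAR[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis."""
    return (3 - codes)[..., ::-1]


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def gc_mask(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of G/C positions."""
    return (codes == 1) | (codes == 2)
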