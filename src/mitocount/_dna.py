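"""Low-level DNA helpers shared by the assembler, classifier and simulator.

Sequences cross module boundaries as plain ``str`` over the alphabet
A/C/G/T/N.  Internally hot paths work on ``numpy.uint8`` code arrays
(A=0, C=1, G=2, T=3, N=4) or on raw ASCII ``bytes``.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4
BASES = "ACGTN"

# ASCII byte -> code; anything unexpected maps to N
_CODE_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
    _CODE_LUT[ord(chr(_b).lower())] = _i

_CHAR_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement over codes: A<->T, C<->G, N->N
_COMP_CODE = np.array([T, G, C, A, N], dtype=np.uint8)

_COMP_TABLE = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE_LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a DNA string."""
    return _CHAR_LUT[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMP_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes[::-1]]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of mismatching positions between two equal-length code arrays."""
    if a.shape != b.shape:
        raise ValueError("hamming: length mismatch")
    return int(np.count_nonzero(a != b))


def circular_slice(codes: np.ndarray, start: int, length: int) -> np.ndarray:
    """Slice ``length`` codes starting at ``start`` with wrap-around."""
    m = codes.shape[0]
    start %= m
    end = start + length
    if end <= m:
        return codes[start:end]
    out = np.empty(length, dtype=np.uint8)
    out[: m - start] = codes[start:]
    rest = codes
    # length may exceed one full extra turn only for pathological inputs
    filled = m - start
    while filled < length:
        take = min(m, length - filled)
        out[filled : filled + take] = rest[:take]
        filled += take
    return out


def validate_alphabet(seq: str, *, allow_n: bool = True, what: str = "sequence") -> None:
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")
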