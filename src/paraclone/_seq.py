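"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base <-> small-int coding used by the numpy fast paths
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Mismatch count between two equal-length encoded sequences."""
    return int(np.count_nonzero(a != b))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))
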