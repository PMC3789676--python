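"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# 256-entry lookup: ASCII byte -> base code 0..3, 255 for anything else.
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes (A=0, C=1, G=2, T=3; other=255)."""
    return _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode()


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def find_sites(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) start positions of ``motif`` in ``seq``."""
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits
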