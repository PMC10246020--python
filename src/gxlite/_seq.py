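"""Low-level nucleotide utilities: 2-bit codes, packing, reverse complement.

Sequences are handled internally as numpy uint8 arrays of base codes
(A=0, C=1, G=2, T=3); any other character maps to INVALID (255).
Complementation is ``3 - code``; the transition-collapsed one-bit
alphabet is ``code & 1`` ({A,G} -> 0, {C,T} -> 1).
"""
from __future__ import annotations

import numpy as np

INVALID = 255

_ENCODE = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (non-ACGT -> INVALID)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGT string (INVALID -> 'N')."""
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    ok = codes < 4
    out[ok] = _DECODE[codes[ok]]
    return out.tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; INVALID stays INVALID."""
    out = codes[::-1].copy()
    ok = out < 4
    out[ok] = 3 - out[ok]
    return out


def pack_2bit(codes: np.ndarray) -> np.ndarray:
    """Pack ACGT codes 4-per-byte. Caller must ensure all codes < 4."""
    if np.any(codes >= 4):
        raise ValueError("cannot 2-bit-pack a sequence containing non-ACGT bases")
    n = len(codes)
    padded = np.zeros((n + 3) // 4 * 4, dtype=np.uint8)
    padded[:n] = codes
    quads = padded.reshape(-1, 4)
    return (
        quads[:, 0] << 6 | quads[:, 1] << 4 | quads[:, 2] << 2 | quads[:, 3]
    ).astype(np.uint8)


def unpack_2bit(packed: np.ndarray, length: int) -> np.ndarray:
    """Inverse of :func:`pack_2bit`; ``length`` recovers the unpadded size."""
    quads = np.empty((len(packed), 4), dtype=np.uint8)
    quads[:, 0] = packed >> 6
    quads[:, 1] = (packed >> 4) & 3
    quads[:, 2] = (packed >> 2) & 3
    quads[:, 3] = packed & 3
    return quads.reshape(-1)[:length].copy()


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    """i.i.d. uniform ACGT codes."""
    return rng.integers(0, 4, size=n, dtype=np.uint8)
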