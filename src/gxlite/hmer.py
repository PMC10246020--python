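"""Locality-sensitive h-mer encoding of nucleotide windows.

An h-mer is a lossy hash of a fixed-length window designed so that the
most frequent cross-species differences are invisible to it:

* every third base of the window (0-based offsets 2, 5, 8, ... — the
  codon-wobble position when the window is in-frame coding sequence) is
  dropped;
* the remaining bases are collapsed to a one-bit purine/pyrimidine
  alphabet ({A,G} -> 0, {C,T} -> 1), so transition substitutions do not
  change the key;
* the key is canonicalized over strands by taking the minimum of the
  hash of the window and of its reverse complement (minword).

With the 56 bp primary window this leaves 38 retained positions, hence
38-bit keys; the 29 bp secondary window leaves 20 positions / 20 bits.
The retained bit-string itself serves as the hash (identity hashing),
which is collision-free at these widths.
"""
from __future__ import annotations

import numpy as np

from ._seq import encode

#: primary (database) window length -> 38 retained bits
PRIMARY_WINDOW = 56
#: secondary (second-pass / repeat-statistics) window length -> 20 bits
SECONDARY_WINDOW = 29


class AmbiguousWindowError(ValueError):
    """Raised when a window contains a non-ACGT symbol."""


def retained_offsets(window_len: int) -> np.ndarray:
    """0-based offsets kept after dropping every third base (i % 3 == 2)."""
    offs = np.arange(window_len)
    return offs[offs % 3 != 2]


def n_retained(window_len: int) -> int:
    return len(retained_offsets(window_len))


def window_keys(codes: np.ndarray, window_len: int):
    """Canonical h-mer keys for every window start of a code array.

    Parameters
    ----------
    codes
        uint8 base codes (INVALID marks ambiguity).
    window_len
        56 (primary) or 29 (secondary); any length >= 3 is accepted.

    Returns
    -------
    keys : uint64 array, one per window start (n - window_len + 1)
    canon_fwd : bool array, True where the forward-strand hash was the
        minimum (i.e. canonical orientation == forward)
    valid : bool array, False where the window contains a non-ACGT base
    """
    n = len(codes) - window_len + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, np.zeros(0, dtype=bool), np.zeros(0, dtype=bool)

    offs = retained_offsets(window_len)
    m = len(offs)
    bad = (codes >= 4).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[window_len:] - cbad[:-window_len]) == 0

    bits = (codes & 1).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    one = np.uint64(1)
    for j, off in enumerate(offs):
        shift = np.uint64(m - 1 - j)
        fwd |= bits[off : off + n] << shift
        # base i of the reverse complement is the complement of base
        # (window_len - 1 - i); complementation flips the one-bit code
        roff = window_len - 1 - off
        rev |= (one - bits[roff : roff + n]) << shift
    keys = np.minimum(fwd, rev)
    canon_fwd = fwd <= rev
    return keys, canon_fwd, valid


def encode_hmer(window: str) -> int:
    """Canonical key of a single window (primary or secondary length).

    Raises
    ------
    AmbiguousWindowError
        if the window contains a character outside ACGT; callers index
        ing a sequence skip such windows.
    """
    codes = encode(window)
    keys, _, valid = window_keys(codes, len(window))
    if not valid[0]:
        raise AmbiguousWindowError(f"window contains non-ACGT symbol: {window!r}")
    return int(keys[0])
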