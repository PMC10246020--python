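"""Query-side sequence conditioning.

Scaffolds are split into contigs on runs of >= 10 Ns (the convention
used to delimit contigs within scaffolds), contigs are chunked into
100 kbp pieces with a 100 bp overlap for bounded-memory alignment, and
two kinds of repeat are soft-masked before seeding:

* low-complexity sequence, by a DUST-like scan: Shannon entropy (base
  2) of the hexamer distribution in a 50 bp sliding window, masked
  where entropy < 4.5 bits;
* transposon-like repeats in eukaryote assemblies, as overrepresented
  h-mers, with counting restricted to sequences of length >=
  min(100 kbp, assembly N80 before N-splitting) so that masses of short
  near-identical contaminant sequences cannot poison the statistics.

Masks are soft: masked windows do not seed, but extensions may cross.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from math import log2
from typing import Iterable, Sequence

import numpy as np

from ._seq import encode
from .hmer import SECONDARY_WINDOW, window_keys, n_retained

logger = logging.getLogger(__name__)

DUST_WINDOW = 50
DUST_THRESHOLD = 4.5
CHUNK_SIZE = 100_000
CHUNK_OVERLAP = 100
N_RUN_MIN = 10


@dataclass
class ContigSpan:
    """A maximal N-run-free span of a parent scaffold."""

    parent_id: str
    start: int  # 0-based inclusive offset in parent
    end: int  # exclusive
    seq: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Chunk:
    contig: ContigSpan
    start: int  # 0-based half-open offsets within the contig
    end: int

    @property
    def seq(self) -> str:
        return self.contig.seq[self.start : self.end]


@dataclass(frozen=True)
class MaskInterval:
    start: int  # 0-based half-open, contig coordinates
    end: int
    kind: str  # "low-complexity" | "transposon"


# Runs of non-ACGT characters; ambiguity codes other than N behave as N
# for splitting when they occur inside such a run.
_N_RUN = re.compile(r"[^ACGTacgt]+")


def split_on_n_runs(
    record_id: str, seq: str, min_run: int = N_RUN_MIN
) -> list[ContigSpan]:
    """Split a scaffold on runs of >= ``min_run`` Ns into contig spans.

    Shorter runs are retained inside spans (they simply produce windows
    that cannot seed). An all-N sequence yields an empty list.
    """
    breaks = [(m.start(), m.end()) for m in _N_RUN.finditer(seq) if m.end() - m.start() >= min_run]
    spans = []
    prev = 0
    for a, b in breaks + [(len(seq), len(seq))]:
        if a > prev:
            spans.append(ContigSpan(record_id, prev, a, seq[prev:a]))
        prev = b
    if not spans:
        logger.info("sequence %s is entirely ambiguous; skipped", record_id)
    return spans


def chunk_contig(
    contig: ContigSpan, size: int = CHUNK_SIZE, overlap: int = CHUNK_OVERLAP
) -> list[Chunk]:
    """Tile a contig into ``size``-bp chunks overlapping by ``overlap``."""
    n = len(contig)
    chunks = []
    start = 0
    while True:
        if start + size >= n:
            chunks.append(Chunk(contig, start, n))
            break
        chunks.append(Chunk(contig, start, start + size))
        start += size - overlap
    return chunks


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def dust_mask(
    seq: str, window: int = DUST_WINDOW, threshold: float = DUST_THRESHOLD
) -> list[MaskInterval]:
    """Low-complexity mask by hexamer Shannon entropy in a sliding window.

    For each window position the entropy (base 2) of the empirical
    distribution of its ``window - 5`` overlapping hexamers is computed
    incrementally; windows below ``threshold`` bits mask their full
    extent, and overlapping masked windows are merged. Hexamers touching
    a non-ACGT base are skipped; a window with no valid hexamer is
    masked.
    """
    n = len(seq)
    if n < 6:
        return []
    codes = encode(seq)
    # hexamer codes via base-4 rolling value; invalid where any base is ambiguous
    ok = codes < 4
    c = np.where(ok, codes, 0).astype(np.int64)
    hexv = (
        (c[:-5] << 10)
        | (c[1:-4] << 8)
        | (c[2:-3] << 6)
        | (c[3:-2] << 4)
        | (c[4:-1] << 2)
        | c[5:]
    )
    okk = ok.astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(okk)])
    hex_valid = (cs[6:] - cs[:-6]) == 6

    if n < window:
        window = n
    nhex_per_win = window - 5
    counts = np.zeros(4096, dtype=np.int64)
    # entropy bookkeeping: H = log2(T) - S/T with S = sum c*log2(c)
    S = 0.0
    T = 0
    _l2 = [0.0, 0.0] + [c_ * log2(c_) for c_ in range(2, window)]

    def add(h):
        nonlocal S, T
        c0 = counts[h]
        S += _l2[c0 + 1] - _l2[c0]
        counts[h] = c0 + 1
        T += 1

    def remove(h):
        nonlocal S, T
        c0 = counts[h]
        S += _l2[c0 - 1] - _l2[c0]
        counts[h] = c0 - 1
        T -= 1

    masked: list[tuple[int, int]] = []
    for j in range(nhex_per_win):
        if hex_valid[j]:
            add(hexv[j])
    n_windows = n - window + 1
    for p in range(n_windows):
        if T == 0:
            low = True
        else:
            low = (log2(T) - S / T) < threshold
        if low:
            masked.append((p, p + window))
        if p + 1 < n_windows:
            if hex_valid[p]:
                remove(hexv[p])
            j = p + nhex_per_win
            if hex_valid[j]:
                add(hexv[j])
    return [MaskInterval(a, b, "low-complexity") for a, b in _merge_intervals(masked)]


def compute_n80(lengths: Sequence[int], fraction: float = 0.8) -> int:
    """Nx length: the size L such that sequences >= L sum to >= x of
    total bases (descending-sort definition)."""
    if not lengths:
        raise ValueError("no sequence lengths supplied")
    arr = np.sort(np.asarray(lengths))[::-1]
    target = fraction * arr.sum()
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, target)])


def transposon_mask(
    records: dict[str, str],
    kingdom: str,
    window_len: int = SECONDARY_WINDOW,
    min_count: int = 8,
    fold: float = 10.0,
    scope_cap: int = 100_000,
) -> dict[str, list[MaskInterval]]:
    """Mask transposon-like repeats as overrepresented h-mers.

    H-mer counts are accumulated (stride 1, secondary window width) only
    over sequences whose pre-splitting length is at least
    min(``scope_cap``, assembly N80); an h-mer is overrepresented when
    its in-scope count reaches ``max(min_count, fold * expected)`` under
    a uniform model over the key space. Positions covered by
    overrepresented h-mers are masked on *all* sequences. No-op for
    prokaryote-like kingdoms.
    """
    from .taxonomy import PROKARYOTE_LIKE

    if kingdom in PROKARYOTE_LIKE:
        return {rid: [] for rid in records}
    lengths = [len(s) for s in records.values()]
    scope = min(scope_cap, compute_n80(lengths))
    per_seq: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    total_windows = 0
    key_space = 1 << n_retained(window_len)
    counts = np.zeros(key_space, dtype=np.int64)
    for rid, seq in records.items():
        codes = encode(seq)
        keys, _, valid = window_keys(codes, window_len)
        per_seq[rid] = (keys, valid)
        if len(seq) >= scope:
            vk = keys[valid]
            counts += np.bincount(vk.astype(np.int64), minlength=key_space)
            total_windows += len(vk)
    if total_windows == 0:
        return {rid: [] for rid in records}
    expected = total_windows / key_space
    threshold = max(min_count, fold * expected)
    over = counts >= threshold
    out: dict[str, list[MaskInterval]] = {}
    for rid, (keys, valid) in per_seq.items():
        hits = np.flatnonzero(valid & over[keys.astype(np.int64)])
        intervals = _merge_intervals((int(i), int(i) + window_len) for i in hits)
        out[rid] = [MaskInterval(a, b, "transposon") for a, b in intervals]
    return out


def mask_to_bool(
    intervals: Iterable[MaskInterval], length: int
) -> np.ndarray:
    """Boolean per-base mask array from intervals."""
    m = np.zeros(length, dtype=bool)
    for iv in intervals:
        m[max(0, iv.start) : min(length, iv.end)] = True
    return m
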