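"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately written in naive string/loop style,
sharing no code path with the package implementation it checks.
"""
from __future__ import annotations

import math
from collections import Counter

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def brute_hmer_key(window: str) -> int:
    """Canonical h-mer key by direct enumeration: retain indices with
    i % 3 != 2, map {A,G}->0 / {C,T}->1, read the bit-string as an
    integer, take the min of forward and reverse complement."""

    def one_strand(w: str) -> int:
        retained = [w[i] for i in range(len(w)) if i % 3 != 2]
        bits = "".join("0" if c in "AG" else "1" for c in retained)
        return int(bits, 2)

    rc = "".join(_COMP[c] for c in reversed(window))
    return min(one_strand(window), one_strand(rc))


def brute_canon_fwd(window: str) -> bool:
    def one_strand(w: str) -> int:
        retained = [w[i] for i in range(len(w)) if i % 3 != 2]
        return int("".join("0" if c in "AG" else "1" for c in retained), 2)

    rc = "".join(_COMP[c] for c in reversed(window))
    return one_strand(window) <= one_strand(rc)


def brute_valid_windows(seq: str, window_len: int) -> list[int]:
    """Window starts whose window is pure ACGT."""
    return [
        p
        for p in range(len(seq) - window_len + 1)
        if all(c in "ACGT" for c in seq[p : p + window_len])
    ]


def brute_seed_set(
    query: str, subject: str, subject_id: str, window_len: int, subject_stride: int
) -> set[tuple[int, str, int, str]]:
    """All-window-pairs seed enumeration: a seed exists wherever the
    canonical keys of a query window (stride 1) and an indexed subject
    window (stride ``subject_stride``) agree."""
    sub_keys = {}
    for p in range(0, len(subject) - window_len + 1, subject_stride):
        w = subject[p : p + window_len]
        if all(c in "ACGT" for c in w):
            sub_keys[p] = (brute_hmer_key(w), brute_canon_fwd(w))
    seeds = set()
    for q in brute_valid_windows(query, window_len):
        wq = query[q : q + window_len]
        kq, cq = brute_hmer_key(wq), brute_canon_fwd(wq)
        for p, (kp, cp) in sub_keys.items():
            if kq != kp:
                continue
            if cq == cp:
                seeds.add((q, subject_id, p, "+"))
            else:
                seeds.add((q, subject_id, len(subject) - p - window_len, "-"))
    return seeds


def brute_filter(
    seeds: set[tuple[int, str, int, str]], diag_tol: int, antidiag_tol: int
) -> set[tuple[int, str, int, str]]:
    """All-pairs application of the two neighbor inequalities within
    each (subject, strand) group."""
    kept = set()
    seeds = list(seeds)
    for i, (q1, sid1, s1, st1) in enumerate(seeds):
        for j, (q2, sid2, s2, st2) in enumerate(seeds):
            if i == j or sid1 != sid2 or st1 != st2:
                continue
            if (
                abs((q1 - s1) - (q2 - s2)) <= diag_tol
                and abs((q1 + s1) - (q2 + s2)) <= antidiag_tol
            ):
                kept.add(seeds[i])
                break
    return kept


def brute_dust_windows(seq: str, window: int = 50, threshold: float = 4.5) -> list[int]:
    """Window starts whose hexamer-distribution entropy is below the
    threshold, by direct per-window recount."""
    low = []
    for p in range(len(seq) - window + 1):
        counts = Counter()
        for j in range(p, p + window - 5):
            h = seq[j : j + 6]
            if all(c in "ACGT" for c in h):
                counts[h] += 1
        total = sum(counts.values())
        if total == 0:
            low.append(p)
            continue
        ent = -sum((c / total) * math.log2(c / total) for c in counts.values())
        if ent < threshold:
            low.append(p)
    return low


def brute_nx(lengths, fraction=0.8) -> int:
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    acc = 0
    for length in ordered:
        acc += length
        if acc >= fraction * total:
            return length
    raise AssertionError("unreachable")


def brute_specificity_bounds(calls, total_bp):
    same = sum(l for l, same_k in calls if same_k)
    cross = sum(l for l, same_k in calls if not same_k)
    return (
        100.0 * (1.0 - same / (total_bp - cross)),
        100.0 * (1.0 - (same + cross) / total_bp),
    )
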