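"""Two-pass seed-and-extend cross-species alignment.

Pass 1 looks up every (unmasked) query window in the reference h-mer
index, noise-filters the resulting seeds by requiring a close neighbor
on the diagonal/antidiagonal, and grows ungapped extensions. Per-taxon
alignment statistics from pass 1 pick the best-matching taxa (top three
under any of four metrics), and pass 2 re-aligns the subject
neighborhoods of those taxa against an on-the-fly 20-bit index of the
query, with gapped extension for refined coverage.

Segment score: sqrt of the sum of squared lengths of the maximal
100%-identity stretches. Compared with a weighted sum of matches and
mismatches, this penalizes broadly distributed mismatches (the
signature of genuine taxonomic distance) more than the same number of
clustered mismatches (often artifacts), because splitting a run always
lowers the score: sqrt(a^2 + b^2) < a + b.

Coordinate conventions: query positions are 0-based on the forward
query. Subject positions are kept in "frame" coordinates — forward
subject for '+' seeds, reverse-complement subject for '-' seeds — so
that colinear matches share a diagonal q - s in both orientations;
reported segments carry forward-subject ranges.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._seq import revcomp
from .hmer import SECONDARY_WINDOW, window_keys
from .refdb import ReferenceDB, _POS_SHIFT, _SUBJ_SHIFT

DIAG_TOL = 1_000
ANTIDIAG_TOL = 10_000
MATCH_SCORE = 1
MISMATCH_SCORE = -3
XDROP = 20
SIG_RUN = 16  # continuation must contain an exact run of this length ...
SIG_WINDOW = 30  # ... within this many aligned columns
INDEL_RADIUS = 10
MIN_SEGMENT_SCORE = 20.0
NEIGHBORHOOD_CAP = 100_000


class Seed(NamedTuple):
    """A query/subject h-mer co-occurrence.

    ``s`` is in frame coordinates (reverse-complement subject
    coordinates when ``strand`` is '-'). ``signed()`` renders the
    1-based strand-signed form (negative subject position = reverse)."""

    q: int
    subject_id: str
    s: int
    strand: str

    def signed(self) -> tuple[int, str, int]:
        return (self.q + 1, self.subject_id, (self.s + 1) if self.strand == "+" else -(self.s + 1))


@dataclass
class AlignmentSegment:
    query_id: str
    q_start: int  # 0-based half-open on the query
    q_end: int
    subject_id: str
    s_start: int  # 0-based half-open, forward subject coordinates
    s_end: int
    strand: str
    identity_runs: list[int]
    score: float
    tax_id: int = 0

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start


@dataclass
class TaxonMetrics:
    """Per-taxon pass-1 statistics driving second-pass taxon selection."""

    tax_id: int
    n_ungapped: int = 0
    max_len: int = 0
    sum_len: int = 0
    sum_len_sq: int = 0

    def add(self, length: int) -> None:
        self.n_ungapped += 1
        self.max_len = max(self.max_len, length)
        self.sum_len += length
        self.sum_len_sq += length * length


def score_segment(identity_runs: Sequence[int]) -> float:
    """sqrt(sum of squared 100%-identity run lengths); empty -> 0."""
    return math.sqrt(sum(r * r for r in identity_runs))


def identity_runs_from_matches(m: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a per-column match array."""
    if len(m) == 0:
        return []
    pad = np.concatenate([[False], m, [False]])
    d = np.diff(pad.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return (ends - starts).tolist()


# ----------------------------------------------------------------- seeds


def lookup_seeds(
    query_codes: np.ndarray,
    db: ReferenceDB,
    mask: np.ndarray | None = None,
    allowed_subjects: np.ndarray | None = None,
) -> list[Seed]:
    """All (query window, posting) co-occurrences at query stride 1.

    Windows containing ambiguity codes or any masked base are skipped.
    ``allowed_subjects`` is an optional boolean array over subject
    indices (False = excluded, e.g. species-dropout mode).
    """
    w = db.window_len
    keys, canon, valid = window_keys(query_codes, w)
    if len(keys) == 0:
        return []
    eligible = valid.copy()
    if mask is not None:
        cm = np.concatenate([[0], np.cumsum(mask.astype(np.int32))])
        eligible &= (cm[w:] - cm[:-w]) == 0
    seeds: list[Seed] = []
    pos_mask = (1 << 32) - 1
    for p in np.flatnonzero(eligible):
        postings = db.lookup(int(keys[p]))
        if len(postings) == 0:
            continue
        qc = bool(canon[p])
        for post in postings:
            post = int(post)
            si = post >> _SUBJ_SHIFT
            if allowed_subjects is not None and not allowed_subjects[si]:
                continue
            pos = (post >> _POS_SHIFT) & pos_mask
            sub = db.subjects[si]
            if qc == bool(post & 1):
                seeds.append(Seed(int(p), sub.subject_id, pos, "+"))
            else:
                seeds.append(Seed(int(p), sub.subject_id, sub.length - pos - w, "-"))
    return seeds


def filter_seeds(
    seeds: Sequence[Seed],
    diag_tol: int = DIAG_TOL,
    antidiag_tol: int = ANTIDIAG_TOL,
) -> list[Seed]:
    """Noise filter: keep a seed iff some *other* seed of the same
    (subject, strand) group lies within ``diag_tol`` on the diagonal
    q - s and ``antidiag_tol`` on the antidiagonal q + s."""
    groups: dict[tuple[str, str], list[int]] = {}
    for i, sd in enumerate(seeds):
        groups.setdefault((sd.subject_id, sd.strand), []).append(i)
    keep = np.zeros(len(seeds), dtype=bool)
    for idxs in groups.values():
        ga = np.array(idxs)
        d = np.array([seeds[i].q - seeds[i].s for i in idxs], dtype=np.int64)
        a = np.array([seeds[i].q + seeds[i].s for i in idxs], dtype=np.int64)
        # grid cells sized exactly (diag_tol, antidiag_tol): two seeds in
        # one cell always satisfy both inequalities, so only singleton
        # cells need the exact check against adjacent cells
        cd = d // diag_tol
        ca = a // antidiag_tol
        cell = cd * (1 << 32) + ca
        order = np.argsort(cell, kind="stable")
        sc, first = np.unique(cell[order], return_index=True)
        counts = np.diff(np.append(first, len(cell)))
        cell_members: dict[int, np.ndarray] = {
            int(c): order[first[k] : first[k] + counts[k]]
            for k, c in enumerate(sc)
        }
        multi = counts[np.searchsorted(sc, cell)] >= 2
        keep[ga[multi]] = True
        for li in np.flatnonzero(~multi):
            di, ai = d[li], a[li]
            found = False
            for gx in (int(cd[li]) - 1, int(cd[li]), int(cd[li]) + 1):
                for gy in (int(ca[li]) - 1, int(ca[li]), int(ca[li]) + 1):
                    members = cell_members.get(gx * (1 << 32) + gy)
                    if members is None:
                        continue
                    near = (np.abs(d[members] - di) <= diag_tol) & (
                        np.abs(a[members] - ai) <= antidiag_tol
                    )
                    near[members == li] = False
                    if near.any():
                        found = True
                        break
                if found:
                    break
            keep[ga[li]] = found
    return [sd for i, sd in enumerate(seeds) if keep[i]]


# ------------------------------------------------------------- extension


def _xdrop_extend(
    qc: np.ndarray,
    sc: np.ndarray,
    q: int,
    s: int,
    xdrop: int = XDROP,
    block: int = 2048,
) -> tuple[int, np.ndarray]:
    """Rightward X-drop ungapped extension from (q, s) inclusive.

    Returns (length, match array of that length). Ambiguity codes count
    as mismatches.
    """
    limit = min(len(qc) - q, len(sc) - s)
    if limit <= 0:
        return 0, np.zeros(0, dtype=bool)
    best_len, best_score, run_score, stopped = 0, 0, 0, False
    pieces = []
    off = 0
    while off < limit and not stopped:
        n = min(block, limit - off)
        a, b = qc[q + off : q + off + n], sc[s + off : s + off + n]
        m = (a == b) & (a < 4)
        pieces.append(m)
        sc_arr = np.where(m, MATCH_SCORE, MISMATCH_SCORE)
        cum = run_score + np.cumsum(sc_arr)
        peak = max(best_score, 0)
        runmax = np.maximum.accumulate(np.maximum(cum, peak))
        fail = np.flatnonzero(runmax - cum > xdrop)
        upto = int(fail[0]) if len(fail) else n
        if upto > 0:
            seg_best = int(np.argmax(cum[:upto]))
            if cum[seg_best] > best_score:
                best_score = int(cum[seg_best])
                best_len = off + seg_best + 1
        if upto < n:
            stopped = True
        run_score = int(cum[-1]) if not stopped else 0
        off += n
    matches = np.concatenate(pieces)[:best_len] if best_len else np.zeros(0, dtype=bool)
    return best_len, matches


def extend_ungapped(
    qc: np.ndarray, sc: np.ndarray, q: int, s: int, xdrop: int = XDROP
) -> tuple[int, int, int, np.ndarray]:
    """Maximal two-sided ungapped extension through seed (q, s).

    Returns (q0, q1, s0, matches) with [q0, q1) on the query, subject
    start s0 on the same diagonal, and the per-column match array.
    """
    rlen, rm = _xdrop_extend(qc, sc, q, s, xdrop)
    llen, lm = _xdrop_extend(qc[::-1], sc[::-1], len(qc) - q, len(sc) - s, xdrop)
    q0, q1 = q - llen, q + rlen
    matches = np.concatenate([lm[::-1], rm])
    return q0, q1, s - llen, matches


def _best_indel_continuation(
    qc: np.ndarray,
    sc: np.ndarray,
    q1: int,
    s1: int,
    indel_radius: int,
    sig_window: int,
    sig_run: int,
):
    """Best continuation (q1, s1 + delta) after the right end of an
    alignment: the indel offset whose next-``sig_window`` columns have
    the highest identity. Returns delta, or None when the winning
    continuation is not significant (no exact run >= sig_run within the
    window)."""
    if len(qc) - q1 < sig_run:
        return None
    best = None
    best_m = None
    for delta in sorted(range(-indel_radius, indel_radius + 1), key=lambda d: (abs(d), d)):
        s = s1 + delta
        if s < 0:
            continue
        n = min(sig_window, len(qc) - q1, len(sc) - s)
        if n < sig_run:
            continue
        a, b = qc[q1 : q1 + n], sc[s : s + n]
        m = (a == b) & (a < 4)
        ident = int(np.count_nonzero(m)) / n
        if best is None or ident > best[0] + 1e-12:
            best = (ident, delta)
            best_m = m
    if best is None:
        return None
    runs = identity_runs_from_matches(best_m)
    if not runs or max(runs) < sig_run:
        return None
    return best[1]


def _gapped_one_side(
    qc: np.ndarray,
    sc: np.ndarray,
    q1: int,
    s1: int,
    cfg_indel: int,
    cfg_sigw: int,
    cfg_sigr: int,
    xdrop: int,
    max_iter: int = 500,
) -> tuple[int, int, list[np.ndarray]]:
    """Iterated indel-and-extend on the right end; returns final
    (q1, s1) and the match-array pieces added (gap columns encoded as a
    single False separator)."""
    pieces: list[np.ndarray] = []
    for _ in range(max_iter):
        delta = _best_indel_continuation(qc, sc, q1, s1, cfg_indel, cfg_sigw, cfg_sigr)
        if delta is None:
            break
        rlen, rm = _xdrop_extend(qc, sc, q1, s1 + delta, xdrop)
        if rlen <= 0:
            break
        if delta != 0:
            pieces.append(np.zeros(1, dtype=bool))  # indel breaks the run
        pieces.append(rm)
        q1 += rlen
        s1 += delta + rlen
    return q1, s1, pieces


def extend_alignment(
    seed: Seed,
    qc: np.ndarray,
    sc_frame: np.ndarray,
    gapped: bool = False,
    xdrop: int = XDROP,
    indel_radius: int = INDEL_RADIUS,
    sig_window: int = SIG_WINDOW,
    sig_run: int = SIG_RUN,
    gap_core_gate: float = 0.0,
) -> tuple[int, int, int, int, list[int]]:
    """Extend a seed into a segment on frame coordinates.

    Returns (q0, q1, s0, s1, identity_runs). ``sc_frame`` must be the
    subject codes in the seed's frame (reverse-complemented for '-').
    ``gap_core_gate`` skips the gapped refinement loop when the
    ungapped core scores below it (spurious small-h-mer collisions are
    not worth indel search).
    """
    q0, q1, s0, matches = extend_ungapped(qc, sc_frame, seed.q, seed.s, xdrop)
    s1 = s0 + (q1 - q0)
    if not gapped:
        return q0, q1, s0, s1, identity_runs_from_matches(matches)
    if gap_core_gate > 0 and score_segment(identity_runs_from_matches(matches)) < gap_core_gate:
        return q0, q1, s0, s1, identity_runs_from_matches(matches)
    col_pieces = [matches]
    q1, s1, right = _gapped_one_side(
        qc, sc_frame, q1, s1, indel_radius, sig_window, sig_run, xdrop
    )
    col_pieces.extend(right)
    # left side: mirror through reversed arrays
    rq, rs = qc[::-1], sc_frame[::-1]
    lq1, ls1, left = _gapped_one_side(
        rq, rs, len(qc) - q0, len(sc_frame) - s0, indel_radius, sig_window, sig_run, xdrop
    )
    q0, s0 = len(qc) - lq1, len(sc_frame) - ls1
    cols = [p[::-1] for p in reversed(left)] + col_pieces
    all_cols = np.concatenate(cols) if cols else np.zeros(0, dtype=bool)
    return q0, q1, s0, s1, identity_runs_from_matches(all_cols)


# ------------------------------------------------------- pass-1 driver


def _frame_to_forward(s0: int, s1: int, strand: str, subject_len: int) -> tuple[int, int]:
    if strand == "+":
        return s0, s1
    return subject_len - s1, subject_len - s0


def align_seeds(
    seeds: Sequence[Seed],
    query_id: str,
    qc: np.ndarray,
    db: ReferenceDB,
    gapped: bool = False,
    min_segment_score: float = MIN_SEGMENT_SCORE,
    xdrop: int = XDROP,
) -> list[AlignmentSegment]:
    """Extend filtered seeds into segments, skipping seeds already
    covered by a previous extension on the same diagonal (ungapped) or
    inside a previous segment's footprint (gapped)."""
    by_group: dict[tuple[str, str], list[Seed]] = {}
    for sd in seeds:
        by_group.setdefault((sd.subject_id, sd.strand), []).append(sd)
    segments: list[AlignmentSegment] = []
    rc_cache: dict[str, np.ndarray] = {}
    for (sid, strand), group in sorted(by_group.items()):
        sub = db.subject(sid)
        sc = sub.codes
        if strand == "-":
            if sid not in rc_cache:
                rc_cache[sid] = revcomp(sub.codes)
            sc = rc_cache[sid]
        group.sort(key=lambda sd: (sd.q - sd.s, sd.q))
        covered: dict[int, int] = {}  # diag -> q covered up to (ungapped)
        # gapped: per-diagonal-band covered query intervals; a gapped
        # segment drifts across diagonals by at most indel_radius per
        # event, so nearby bands are checked too
        gcov: dict[int, list[tuple[int, int]]] = {}
        slack = INDEL_RADIUS + 6
        for sd in group:
            diag = sd.q - sd.s
            if not gapped:
                if covered.get(diag, -1) >= sd.q:
                    continue
            else:
                hit = False
                for dd in range(diag - slack, diag + slack + 1):
                    for a, b in gcov.get(dd, ()):
                        if a <= sd.q < b:
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    continue
            q0, q1, s0, s1, runs = extend_alignment(
                sd, qc, sc, gapped=gapped, xdrop=xdrop,
                gap_core_gate=min_segment_score * 0.5,
            )
            if q1 <= q0:
                if not gapped:
                    covered[diag] = max(covered.get(diag, -1), sd.q)
                else:
                    gcov.setdefault(diag, []).append((sd.q, sd.q + 1))
                continue
            if not gapped:
                covered[diag] = max(covered.get(diag, -1), q1)
            else:
                for dd in (q0 - s0, q1 - s1):
                    gcov.setdefault(dd, []).append((q0, q1))
            sc_val = score_segment(runs)
            if sc_val < min_segment_score:
                continue
            fs0, fs1 = _frame_to_forward(s0, s1, strand, sub.length)
            segments.append(
                AlignmentSegment(
                    query_id, q0, q1, sid, fs0, fs1, strand, runs, sc_val, sub.tax_id
                )
            )
    return segments


def merge_chunk_segments(
    segments: Sequence[AlignmentSegment],
    db: ReferenceDB,
    qc: np.ndarray,
    diag_slack: int = 10,
) -> list[AlignmentSegment]:
    """Fuse ungapped segments from adjacent chunks that lie on the same
    (subject, strand) diagonal (within ``diag_slack``) with abutting or
    overlapping query ranges, recomputing identity runs over the fused
    range; drop duplicates from the 100 bp chunk overlap."""
    out: list[AlignmentSegment] = []
    by_key: dict[tuple[str, str], list[AlignmentSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.subject_id, seg.strand), []).append(seg)
    rc_cache: dict[str, np.ndarray] = {}
    for (sid, strand), segs in sorted(by_key.items()):
        sub = db.subject(sid)
        sc = sub.codes
        if strand == "-":
            if sid not in rc_cache:
                rc_cache[sid] = revcomp(sub.codes)
            sc = rc_cache[sid]

        def frame_start(seg: AlignmentSegment) -> int:
            if strand == "+":
                return seg.s_start
            return sub.length - seg.s_end

        segs.sort(key=lambda g: (g.q_start - frame_start(g), g.q_start))
        merged: list[list[int]] = []  # [q0, q1, s0(frame), diag]
        for seg in segs:
            fs = frame_start(seg)
            diag = seg.q_start - fs
            if merged and abs(diag - merged[-1][3]) <= diag_slack and seg.q_start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], seg.q_end)
            else:
                merged.append([seg.q_start, seg.q_end, fs, diag])
        for q0, q1, s0, diag in merged:
            n = q1 - q0
            a = qc[q0:q1]
            b = sc[s0 : s0 + n]
            n2 = min(len(a), len(b))
            m = (a[:n2] == b[:n2]) & (a[:n2] < 4)
            runs = identity_runs_from_matches(m)
            fs0, fs1 = _frame_to_forward(s0, s0 + n2, strand, sub.length)
            out.append(
                AlignmentSegment(
                    segs[0].query_id, q0, q0 + n2, sid, fs0, fs1, strand,
                    runs, score_segment(runs), sub.tax_id,
                )
            )
    return out


# ----------------------------------------------- per-taxon reductions


def best_per_taxon(segments: Sequence[AlignmentSegment]) -> list[AlignmentSegment]:
    """Within each taxon keep, greedily by descending score, only
    segments that do not overlap an already-kept segment on query
    coordinates; non-overlapping segments all survive."""
    by_tax: dict[int, list[AlignmentSegment]] = {}
    for seg in segments:
        by_tax.setdefault(seg.tax_id, []).append(seg)
    out: list[AlignmentSegment] = []
    for segs in by_tax.values():
        segs = sorted(segs, key=lambda g: (-g.score, g.q_start, g.q_end))
        kept: list[AlignmentSegment] = []
        for seg in segs:
            if not any(seg.q_start < k.q_end and k.q_start < seg.q_end for k in kept):
                kept.append(seg)
        out.extend(kept)
    out.sort(key=lambda g: (g.query_id, g.q_start, g.subject_id))
    return out


def collect_taxon_metrics(
    segments: Sequence[AlignmentSegment],
) -> dict[int, TaxonMetrics]:
    metrics: dict[int, TaxonMetrics] = {}
    for seg in segments:
        metrics.setdefault(seg.tax_id, TaxonMetrics(seg.tax_id)).add(seg.q_len)
    return metrics


def select_second_pass_taxa(
    metrics: Iterable[TaxonMetrics], top_n: int = 3
) -> set[int]:
    """Union of the taxa placed in the top ``top_n`` of any of the four
    pass-1 metrics; all taxa tying the ``top_n``-th value are included."""
    ms = list(metrics)
    selected: set[int] = set()
    for attr in ("n_ungapped", "max_len", "sum_len", "sum_len_sq"):
        vals = sorted((getattr(m, attr) for m in ms), reverse=True)
        if not vals:
            continue
        cutoff = vals[min(top_n, len(vals)) - 1]
        selected.update(m.tax_id for m in ms if getattr(m, attr) >= cutoff)
    return selected


# ------------------------------------------------------- second pass


def build_query_index(
    qc: np.ndarray,
    mask: np.ndarray | None = None,
    window_len: int = SECONDARY_WINDOW,
) -> dict[int, list[tuple[int, bool]]]:
    """20-bit h-mer index of a query contig at stride 1."""
    keys, canon, valid = window_keys(qc, window_len)
    eligible = valid
    if mask is not None:
        cm = np.concatenate([[0], np.cumsum(mask.astype(np.int32))])
        eligible = valid & ((cm[window_len:] - cm[:-window_len]) == 0)
    index: dict[int, list[tuple[int, bool]]] = {}
    for p in np.flatnonzero(eligible):
        index.setdefault(int(keys[p]), []).append((int(p), bool(canon[p])))
    return index


def subject_neighborhoods(
    segments: Sequence[AlignmentSegment],
    query_len: int,
    cap: int = NEIGHBORHOOD_CAP,
) -> dict[str, list[tuple[int, int]]]:
    """Subject ranges around pass-1 hit footprints, each expanded to at
    most min(cap, 2 * query length) centered on the footprint, merged
    per subject when touching."""
    limit = min(cap, 2 * query_len)
    by_subject: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        mid = (seg.s_start + seg.s_end) // 2
        half = max(limit, seg.s_end - seg.s_start) // 2
        by_subject.setdefault(seg.subject_id, []).append((mid - half, mid + half))
    merged = {}
    for sid, ranges in by_subject.items():
        out: list[list[int]] = []
        for a, b in sorted(ranges):
            if out and a <= out[-1][1]:
                out[-1][1] = max(out[-1][1], b)
            else:
                out.append([a, b])
        merged[sid] = [(a, b) for a, b in out]
    return merged


def second_pass_align(
    query_id: str,
    qc: np.ndarray,
    db: ReferenceDB,
    selected_taxa: set[int],
    pass1_segments: Sequence[AlignmentSegment],
    mask: np.ndarray | None = None,
    window_len: int = SECONDARY_WINDOW,
    diag_tol: int = DIAG_TOL,
    antidiag_tol: int = ANTIDIAG_TOL,
    min_segment_score: float = MIN_SEGMENT_SCORE,
    neighborhood_cap: int = NEIGHBORHOOD_CAP,
) -> list[AlignmentSegment]:
    """Gapped re-alignment of selected-taxon subject neighborhoods
    against an on-the-fly small-h-mer index of the query."""
    if not selected_taxa:
        return []
    qindex = build_query_index(qc, mask, window_len)
    if not qindex:
        return []
    relevant = [s for s in pass1_segments if s.tax_id in selected_taxa]
    hoods = subject_neighborhoods(relevant, len(qc), neighborhood_cap)
    seeds: list[Seed] = []
    for sid, ranges in hoods.items():
        sub = db.subject(sid)
        for a, b in ranges:
            a, b = max(0, a), min(sub.length, b)
            if b - a < window_len:
                continue
            keys, canon, valid = window_keys(sub.codes[a:b], window_len)
            for p in np.flatnonzero(valid):
                hits = qindex.get(int(keys[p]))
                if not hits:
                    continue
                spos = a + int(p)
                sflag = bool(canon[p])
                for qpos, qflag in hits:
                    if qflag == sflag:
                        seeds.append(Seed(qpos, sid, spos, "+"))
                    else:
                        seeds.append(Seed(qpos, sid, sub.length - spos - window_len, "-"))
    seeds = filter_seeds(seeds, diag_tol, antidiag_tol)
    return align_seeds(
        seeds, query_id, qc, db, gapped=True, min_segment_score=min_segment_score
    )
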