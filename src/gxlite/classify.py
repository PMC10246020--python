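"""Taxonomic assignment of query sequences from alignment evidence.

Per sequence, alignment coverage and score are reported for at most
four species, at most two per taxonomic division (a second species in
the same division helps distinguish genuine contaminants from isolated
contamination in the reference database itself). Genome-wide, the
division with the highest coverage anchors a set of *inferred primary
divisions*: divisions from the same kingdom whose aligned intervals
largely overlap the top division's are treated as belonging to the
declared source organism, with the required concordance relaxed for
genomes that are poorly represented in the database. Aggregate
coverage (total length aligned to the top four hits over total genome
size) gates contaminant calling entirely, restricting calls to
high-confidence cases when the database has few close neighbors.

Each sequence then lands in one of three categories: primary-division
(consistent with the declared tax-id), contaminant (conclusively in a
non-primary division), or inconclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .aligner import AlignmentSegment, score_segment
from .config import GxConfig
from .taxonomy import Taxonomy

MAX_SPECIES_PER_SEQ = 4
MAX_SPECIES_PER_DIVISION = 2


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def interval_len(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(b - a for a, b in intervals)


def interval_subtract(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Pieces of the (merged, sorted) intervals ``a`` not covered by
    ``b``."""
    out: list[tuple[int, int]] = []
    for lo, hi in a:
        cur = lo
        for blo, bhi in b:
            if bhi <= cur or blo >= hi:
                continue
            if blo > cur:
                out.append((cur, blo))
            cur = max(cur, bhi)
            if cur >= hi:
                break
        if cur < hi:
            out.append((cur, hi))
    return out


def intersect_len(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass
class HitEntry:
    """Evidence for one species on one sequence."""

    tax_id: int
    division: str
    kingdom: str
    coverage_len: int
    score: float
    intervals: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SequenceEvidence:
    seq_id: str
    length: int
    hits: list[HitEntry] = field(default_factory=list)


@dataclass
class GenomeContext:
    declared_tax_id: int
    declared_division: str
    declared_kingdom: str
    primary_set: set[str]
    aggregate_coverage: float
    min_coverage_cutoff: float
    division_coverage: dict[str, int] = field(default_factory=dict)
    total_length: int = 0
    swapped: bool = False
    low_coverage: bool = False
    warning: str | None = None

    @property
    def effective_primary_set(self) -> set[str]:
        """Divisions treated as the source organism when calling.

        In swapped mode (declared division well-represented yet
        unsupported by the assembly) the computed primary set is
        reported as contamination, so only the declared division
        remains primary."""
        return {self.declared_division} if self.swapped else self.primary_set


@dataclass
class SequenceCall:
    seq_id: str
    length: int
    category: str  # "primary-division" | "contaminant" | "inconclusive"
    call_division: str | None = None
    contaminant_spans: list[tuple[int, int]] = field(default_factory=list)
    top_hit: HitEntry | None = None
    # sub-threshold foreign evidence retained for the REVIEW pathway
    weak_foreign: HitEntry | None = None
    weak_spans: list[tuple[int, int]] = field(default_factory=list)


def summarize_hits(
    seq_id: str,
    length: int,
    segments: Sequence[AlignmentSegment],
    taxonomy: Taxonomy,
) -> SequenceEvidence:
    """Collapse one sequence's segments to ranked per-species evidence,
    truncated to 4 species overall and 2 per division."""
    by_tax: dict[int, list[AlignmentSegment]] = {}
    for seg in segments:
        by_tax.setdefault(seg.tax_id, []).append(seg)
    entries = []
    for tax_id, segs in by_tax.items():
        intervals = merge_intervals((s.q_start, s.q_end) for s in segs)
        runs: list[int] = []
        for s in segs:
            runs.extend(s.identity_runs)
        entries.append(
            HitEntry(
                tax_id,
                taxonomy.division(tax_id),
                taxonomy.kingdom(tax_id),
                interval_len(intervals),
                score_segment(runs),
                intervals,
            )
        )
    entries.sort(key=lambda h: (-h.coverage_len, -h.score, h.tax_id))
    kept: list[HitEntry] = []
    per_div: dict[str, int] = {}
    for h in entries:
        if len(kept) >= MAX_SPECIES_PER_SEQ:
            break
        if per_div.get(h.division, 0) >= MAX_SPECIES_PER_DIVISION:
            continue
        kept.append(h)
        per_div[h.division] = per_div.get(h.division, 0) + 1
    return SequenceEvidence(seq_id, length, kept)


def _dynamic_concordance(aggregate_coverage: float, cfg: GxConfig) -> float:
    """Required overlap for a division to join the primary set; relaxed
    linearly as aggregate coverage falls (poorly represented species)."""
    c = aggregate_coverage
    lo, hi = cfg.concordance_cov_low, cfg.concordance_cov_high
    if c >= hi:
        return cfg.concordance_high
    if c <= lo:
        return cfg.concordance_low
    t = (c - lo) / (hi - lo)
    return cfg.concordance_low + t * (cfg.concordance_high - cfg.concordance_low)


def infer_primary_divisions(
    evidences: Mapping[str, SequenceEvidence],
    declared_tax_id: int,
    taxonomy: Taxonomy,
    cfg: GxConfig,
) -> GenomeContext:
    """Genome-wide context: aggregate coverage, top-coverage division,
    and the inferred primary-division set (same-kingdom divisions whose
    alignments sufficiently overlap the top division's)."""
    declared_division = taxonomy.division(declared_tax_id)
    declared_kingdom = taxonomy.kingdom(declared_tax_id)
    total_len = sum(e.length for e in evidences.values())
    div_intervals: dict[str, dict[str, list[tuple[int, int]]]] = {}
    aligned_total = 0
    for sid, ev in evidences.items():
        all_iv: list[tuple[int, int]] = []
        for h in ev.hits:
            all_iv.extend(h.intervals)
            div_intervals.setdefault(h.division, {}).setdefault(sid, []).extend(
                h.intervals
            )
        aligned_total += interval_len(merge_intervals(all_iv))
    div_cov = {
        d: sum(interval_len(merge_intervals(iv)) for iv in per_seq.values())
        for d, per_seq in div_intervals.items()
    }
    aggregate_coverage = aligned_total / total_len if total_len else 0.0
    ctx = GenomeContext(
        declared_tax_id,
        declared_division,
        declared_kingdom,
        primary_set={declared_division},
        aggregate_coverage=aggregate_coverage,
        min_coverage_cutoff=cfg.min_coverage_cutoff,
        division_coverage=div_cov,
        total_length=total_len,
    )
    if not div_cov:
        ctx.low_coverage = True
        return ctx
    top_div = max(div_cov, key=lambda d: (div_cov[d], d))
    top_kingdom = taxonomy.kingdom_of_division(top_div)
    top_per_seq = {
        sid: merge_intervals(iv) for sid, iv in div_intervals[top_div].items()
    }
    threshold = _dynamic_concordance(aggregate_coverage, cfg)
    primary = {top_div}
    for d, per_seq in div_intervals.items():
        if d == top_div:
            continue
        if taxonomy.kingdom_of_division(d) != top_kingdom:
            continue  # kingdom gate: never cross kingdoms into the primary set
        cov = div_cov[d]
        if cov == 0:
            continue
        overlap = sum(
            intersect_len(merge_intervals(iv), top_per_seq.get(sid, []))
            for sid, iv in per_seq.items()
        )
        if overlap / cov >= threshold:
            primary.add(d)
    ctx.primary_set = primary
    return ctx


def check_declared_taxon(
    ctx: GenomeContext, taxonomy: Taxonomy, cfg: GxConfig
) -> GenomeContext:
    """Sanity-check the user-asserted tax-id against the evidence.

    If the declared division is well-represented in the database yet
    the assembly shows (almost) no coverage from it, the computed
    primary divisions are reported as contaminants and a warning is
    attached (likely wrong tax-id or overwhelming contamination). A
    poorly represented declared division instead keeps calls
    conservative: the declared division joins the primary set.
    """
    if ctx.declared_division in ctx.primary_set:
        return ctx
    species_counts = taxonomy.species_count_per_division()
    well_represented = (
        species_counts.get(ctx.declared_division, 0)
        >= cfg.well_represented_min_species
    )
    declared_cov = ctx.division_coverage.get(ctx.declared_division, 0)
    declared_frac = declared_cov / ctx.total_length if ctx.total_length else 0.0
    poor = declared_frac < max(
        cfg.declared_poor_abs, cfg.declared_poor_rel * ctx.aggregate_coverage
    )
    if well_represented and poor and ctx.aggregate_coverage > 0:
        ctx.swapped = True
        ctx.warning = (
            f"declared division {ctx.declared_division!r} is well-represented in "
            f"the database but covers only {declared_frac:.1%} of the assembly; "
            f"divisions {sorted(ctx.primary_set)} are reported as contaminants — "
            "check the supplied tax-id"
        )
    else:
        ctx.primary_set.add(ctx.declared_division)
        if ctx.aggregate_coverage < ctx.min_coverage_cutoff:
            ctx.low_coverage = True
    return ctx


def call_sequence(
    evidence: SequenceEvidence, ctx: GenomeContext, cfg: GxConfig
) -> SequenceCall:
    """Assign one sequence to primary-division / contaminant /
    inconclusive.

    A contaminant call requires conclusive foreign evidence, judged two
    ways, and genome aggregate coverage above the minimum cutoff:

    * whole-sequence: the foreign division covers at least
      ``min_contam_cov_frac`` of the sequence and its score is at least
      ``contam_score_ratio`` times the best primary-set score;
    * chimeric: the foreign spans are locally foreign — at least
      ``min_chimera_span`` bp lies outside primary-division coverage
      and primary alignments overlap at most
      ``max_primary_overlap_frac`` of the foreign spans.

    Sub-threshold foreign evidence is kept on the call for the
    downstream REVIEW pathway.
    """
    call = SequenceCall(evidence.seq_id, evidence.length, "inconclusive")
    if not evidence.hits:
        return call
    primary_set = ctx.effective_primary_set
    primary_hits = [h for h in evidence.hits if h.division in primary_set]
    foreign_hits = [h for h in evidence.hits if h.division not in primary_set]
    best_primary_score = max((h.score for h in primary_hits), default=0.0)
    call.top_hit = evidence.hits[0]
    if foreign_hits:
        top_foreign = foreign_hits[0]
        div_spans = merge_intervals(
            iv
            for h in foreign_hits
            if h.division == top_foreign.division
            for iv in h.intervals
        )
        cov_frac = interval_len(div_spans) / evidence.length
        whole_seq = (
            cov_frac >= cfg.min_contam_cov_frac
            and top_foreign.score >= cfg.contam_score_ratio * best_primary_score
        )
        primary_iv = merge_intervals(
            iv for h in primary_hits for iv in h.intervals
        )
        exclusive = interval_subtract(div_spans, primary_iv)
        span_len = interval_len(div_spans)
        overlap_frac = 1.0 - interval_len(exclusive) / span_len if span_len else 1.0
        chimeric = (
            interval_len(exclusive) >= cfg.min_chimera_span
            and overlap_frac <= cfg.max_primary_overlap_frac
        )
        if (whole_seq or chimeric) and ctx.aggregate_coverage >= ctx.min_coverage_cutoff:
            call.category = "contaminant"
            call.call_division = top_foreign.division
            call.contaminant_spans = (
                div_spans
                if whole_seq
                else [
                    iv for iv in exclusive
                    if iv[1] - iv[0] >= cfg.min_chimera_span
                ]
            )
            call.top_hit = top_foreign
            return call
        call.weak_foreign = top_foreign
        call.weak_spans = div_spans
    if primary_hits:
        call.category = "primary-division"
        call.call_division = primary_hits[0].division
        call.top_hit = primary_hits[0]
    return call
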