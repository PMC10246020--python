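"""End-to-end screening: preprocess -> align -> classify -> actions.

``screen_assembly`` is the library entry point behind the ``screen``
CLI subcommand: it conditions the query (N-splitting, chunking,
masking), runs the two alignment passes against the reference
database, infers the genome context and per-sequence calls, and emits
action records plus a machine-readable summary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import aligner, preprocess
from ._seq import encode
from .actions import (
    ActionRecord,
    REVIEW_CLASS,
    assign_action,
    compute_genome_totals,
)
from .classify import (
    GenomeContext,
    SequenceCall,
    SequenceEvidence,
    call_sequence,
    check_declared_taxon,
    infer_primary_divisions,
    summarize_hits,
)
from .config import GxConfig
from .refdb import ReferenceDB
from .taxonomy import PROKARYOTE_LIKE

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    declared_tax_id: int
    context: GenomeContext
    evidence: dict[str, SequenceEvidence]
    calls: dict[str, SequenceCall]
    action_records: list[ActionRecord]
    segments: dict[str, list[aligner.AlignmentSegment]] = field(default_factory=dict)

    def summary(self) -> dict:
        contam_bp_by_kingdom: dict[str, int] = {}
        for rec in self.action_records:
            if rec.action in REVIEW_CLASS:
                continue
            k = self._kingdom_of(rec.division)
            contam_bp_by_kingdom[k] = (
                contam_bp_by_kingdom.get(k, 0) + rec.end_pos - rec.start_pos + 1
            )
        return {
            "declared_tax_id": self.declared_tax_id,
            "declared_division": self.context.declared_division,
            "primary_divisions": sorted(self.context.primary_set),
            "aggregate_coverage": round(self.context.aggregate_coverage, 4),
            "n_sequences": len(self.calls),
            "n_contaminant_sequences": sum(
                1 for c in self.calls.values() if c.category == "contaminant"
            ),
            "n_action_records": len(self.action_records),
            "contaminant_bp_removed_by_kingdom": contam_bp_by_kingdom,
            "warning": self.context.warning,
        }

    def _kingdom_of(self, division: str) -> str:
        return self._taxonomy.kingdom_of_division(division)

    _taxonomy = None  # set by screen_assembly


def _allowed_subjects(db: ReferenceDB, cfg: GxConfig) -> np.ndarray | None:
    if not cfg.exclude_tax_ids:
        return None
    return np.array(
        [s.tax_id not in cfg.exclude_tax_ids for s in db.subjects], dtype=bool
    )


def align_record(
    record_id: str,
    seq: str,
    db: ReferenceDB,
    cfg: GxConfig,
    transposon_intervals: Sequence[preprocess.MaskInterval] = (),
    allowed: np.ndarray | None = None,
) -> list[aligner.AlignmentSegment]:
    """Two-pass alignment of one query record; segments in record
    coordinates."""
    contigs = preprocess.split_on_n_runs(record_id, seq)
    pass1: list[aligner.AlignmentSegment] = []
    contig_data = []
    for contig in contigs:
        qc = encode(contig.seq)
        mask = np.zeros(len(contig), dtype=bool)
        if cfg.mask_low_complexity:
            for iv in preprocess.dust_mask(contig.seq, cfg.dust_window, cfg.dust_threshold):
                mask[iv.start : iv.end] = True
        for iv in transposon_intervals:
            a = max(iv.start - contig.start, 0)
            b = min(iv.end - contig.start, len(contig))
            if a < b:
                mask[a:b] = True
        contig_segments: list[aligner.AlignmentSegment] = []
        for chunk in preprocess.chunk_contig(contig):
            ckc = qc[chunk.start : chunk.end]
            cmask = mask[chunk.start : chunk.end]
            seeds = aligner.lookup_seeds(ckc, db, cmask, allowed)
            seeds = aligner.filter_seeds(seeds, cfg.diag_tol, cfg.antidiag_tol)
            segs = aligner.align_seeds(
                seeds, record_id, ckc, db,
                gapped=False, min_segment_score=cfg.min_segment_score,
                xdrop=cfg.xdrop,
            )
            for s in segs:  # chunk -> contig coordinates
                s.q_start += chunk.start
                s.q_end += chunk.start
            contig_segments.extend(segs)
        contig_segments = aligner.merge_chunk_segments(contig_segments, db, qc)
        contig_segments = aligner.best_per_taxon(contig_segments)
        contig_data.append((contig, qc, mask, contig_segments))
        pass1.extend(
            _shift(s, contig.start) for s in contig_segments
        )

    metrics = aligner.collect_taxon_metrics(pass1)
    selected = aligner.select_second_pass_taxa(metrics.values())
    final: list[aligner.AlignmentSegment] = []
    for contig, qc, mask, contig_segments in contig_data:
        pass2 = aligner.second_pass_align(
            record_id, qc, db, selected, contig_segments, mask,
            diag_tol=cfg.diag_tol, antidiag_tol=cfg.antidiag_tol,
            min_segment_score=cfg.min_segment_score,
            neighborhood_cap=cfg.neighborhood_cap,
        )
        combined = aligner.best_per_taxon(contig_segments + pass2)
        final.extend(_shift(s, contig.start) for s in combined)
    return final


def _shift(seg: aligner.AlignmentSegment, offset: int) -> aligner.AlignmentSegment:
    if offset == 0:
        return seg
    return aligner.AlignmentSegment(
        seg.query_id, seg.q_start + offset, seg.q_end + offset,
        seg.subject_id, seg.s_start, seg.s_end, seg.strand,
        seg.identity_runs, seg.score, seg.tax_id,
    )


def screen_assembly(
    records: Mapping[str, str],
    declared_tax_id: int,
    db: ReferenceDB,
    cfg: GxConfig | None = None,
) -> ScreenResult:
    cfg = cfg or GxConfig()
    if declared_tax_id not in db.taxonomy:
        raise ValueError(f"unknown tax-id {declared_tax_id}")
    declared_kingdom = db.taxonomy.kingdom(declared_tax_id)
    transposon: dict[str, list[preprocess.MaskInterval]] = {r: [] for r in records}
    if cfg.mask_transposons and declared_kingdom not in PROKARYOTE_LIKE:
        transposon = preprocess.transposon_mask(
            dict(records), declared_kingdom,
            min_count=cfg.transposon_min_count, fold=cfg.transposon_fold,
        )
    allowed = _allowed_subjects(db, cfg)

    evidence: dict[str, SequenceEvidence] = {}
    segments: dict[str, list[aligner.AlignmentSegment]] = {}
    for rid, seq in records.items():
        segs = align_record(rid, seq, db, cfg, transposon.get(rid, ()), allowed)
        segments[rid] = segs
        evidence[rid] = summarize_hits(rid, len(seq), segs, db.taxonomy)

    ctx = infer_primary_divisions(evidence, declared_tax_id, db.taxonomy, cfg)
    ctx = check_declared_taxon(ctx, db.taxonomy, cfg)
    calls = {rid: call_sequence(ev, ctx, cfg) for rid, ev in evidence.items()}
    totals = compute_genome_totals(
        list(calls.values()), ctx, db.taxonomy, sum(len(s) for s in records.values())
    )
    action_records: list[ActionRecord] = []
    for rid in records:
        action_records.extend(
            assign_action(calls[rid], ctx, totals, db.taxonomy, cfg)
        )
    action_records.sort(key=lambda r: (r.seq_id, r.start_pos, r.end_pos))
    result = ScreenResult(
        declared_tax_id, ctx, evidence, calls, action_records, segments
    )
    result._taxonomy = db.taxonomy
    return result
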