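"""Map sequence calls to cleaning actions and apply them.

Six actions: EXCLUDE (drop the whole sequence), TRIM (remove a terminal
contaminant span), FIX (excise an internal span and split the
remainder) are high-confidence and executed automatically; REVIEW,
REVIEW_RARE and INFO flag sequences for human inspection and never
modify the FASTA. Gates:

* a same-kingdom chimeric span must reach 10 kb to be reported at all,
  and is then REVIEW rather than corrective;
* chimeras whose contaminant division is on the known-LGT list for the
  host kingdom (e.g. alphaproteobacterial endosymbiont integrants in
  invertebrates) are INFO;
* prokaryote-in-prokaryote contamination totaling under 1% of the
  assembly is REVIEW_RARE (computed on total assembly length before
  any cleaning);
* low-coverage foreign evidence is REVIEW only when its division has a
  conclusive contaminant call elsewhere in the genome.

Report coordinates are 1-based inclusive; a record spanning less than
the whole sequence (start_pos + end_pos != 1 + length for a full span)
describes a chimeric range.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .classify import GenomeContext, SequenceCall, interval_len
from .config import GxConfig
from .taxonomy import PROKARYOTES, Taxonomy

CORRECTIVE = frozenset({"EXCLUDE", "TRIM", "FIX"})
REVIEW_CLASS = frozenset({"REVIEW", "REVIEW_RARE", "INFO"})
ACTIONS = CORRECTIVE | REVIEW_CLASS


@dataclass
class ActionRecord:
    seq_id: str
    start_pos: int  # 1-based inclusive
    end_pos: int
    seq_length: int
    action: str
    division: str
    top_tax_id: int
    coverage_len: int
    score: float

    def __post_init__(self):
        if not (1 <= self.start_pos <= self.end_pos <= self.seq_length):
            raise ValueError(f"invalid span on {self.seq_id}: {self}")
        if self.action == "EXCLUDE" and (
            self.start_pos != 1 or self.end_pos != self.seq_length
        ):
            raise ValueError("EXCLUDE must span the whole sequence")


@dataclass
class GenomeTotals:
    """Assembly-level quantities the action gates depend on, computed
    over all conclusive calls before any action is assigned."""

    assembly_bp: int
    prok_in_prok_bp: int
    divisions_with_conclusive: set[str]


def compute_genome_totals(
    calls: Sequence[SequenceCall],
    ctx: GenomeContext,
    taxonomy: Taxonomy,
    assembly_bp: int,
) -> GenomeTotals:
    host_prok = ctx.declared_kingdom in PROKARYOTES
    prok_bp = 0
    divisions = set()
    for c in calls:
        if c.category != "contaminant":
            continue
        divisions.add(c.call_division)
        if host_prok and taxonomy.kingdom_of_division(c.call_division) in PROKARYOTES:
            prok_bp += interval_len(c.contaminant_spans)
    return GenomeTotals(assembly_bp, prok_bp, divisions)


def _is_lgt(division: str, host_kingdom: str, cfg: GxConfig) -> bool:
    return any(
        division == d and host_kingdom == k for d, k in cfg.lgt_pairs
    )


def assign_action(
    call: SequenceCall,
    ctx: GenomeContext,
    totals: GenomeTotals,
    taxonomy: Taxonomy,
    cfg: GxConfig,
) -> list[ActionRecord]:
    """Action records for one sequence call (possibly empty: suppressed
    same-kingdom short chimeras, or clean/inconclusive sequences with
    no reviewable evidence)."""
    records: list[ActionRecord] = []
    L = call.length
    host_kingdom = ctx.declared_kingdom

    if call.category == "contaminant":
        division = call.call_division
        contam_kingdom = taxonomy.kingdom_of_division(division)
        hit = call.top_hit
        prok_rare = (
            host_kingdom in PROKARYOTES
            and contam_kingdom in PROKARYOTES
            and totals.prok_in_prok_bp < cfg.rare_prok_frac * totals.assembly_bp
        )
        covered = interval_len(call.contaminant_spans)
        if covered >= cfg.exclude_cov_frac * L:
            action = "REVIEW_RARE" if prok_rare else "EXCLUDE"
            records.append(
                ActionRecord(
                    call.seq_id, 1, L, L, action, division,
                    hit.tax_id, hit.coverage_len, round(hit.score, 1),
                )
            )
            return records
        for a, b in call.contaminant_spans:
            span_len = b - a
            if contam_kingdom == host_kingdom:
                if span_len < cfg.same_kingdom_chimera_min:
                    continue  # suppressed: short same-kingdom chimeric span
                action = "REVIEW"
            elif _is_lgt(division, host_kingdom, cfg):
                action = "INFO"
            elif prok_rare:
                action = "REVIEW_RARE"
            elif a <= cfg.trim_end_slack or b >= L - cfg.trim_end_slack:
                action = "TRIM"
            else:
                action = "FIX"
            records.append(
                ActionRecord(
                    call.seq_id, a + 1, b, L, action, division,
                    hit.tax_id, hit.coverage_len, round(hit.score, 1),
                )
            )
        return records

    # low-coverage foreign evidence: REVIEW when the division shows
    # conclusive contamination elsewhere in the genome
    if call.weak_foreign is not None and call.weak_spans:
        division = call.weak_foreign.division
        if division in totals.divisions_with_conclusive:
            a = min(s for s, _ in call.weak_spans)
            b = max(e for _, e in call.weak_spans)
            records.append(
                ActionRecord(
                    call.seq_id, a + 1, b, L, "REVIEW", division,
                    call.weak_foreign.tax_id,
                    call.weak_foreign.coverage_len,
                    round(call.weak_foreign.score, 1),
                )
            )
    return records


# ---------------------------------------------------------- cleaning


@dataclass
class CleanResult:
    kept: dict[str, str]
    removed: list[tuple[str, str]]  # (provenance defline, sequence)
    total_removed_bp: int = 0
    n_excluded: int = 0
    n_trimmed: int = 0
    n_fixed: int = 0
    n_dropped_short: int = 0

    @property
    def kept_bp(self) -> int:
        return sum(len(s) for s in self.kept.values())

    @property
    def removed_bp(self) -> int:
        return sum(len(s) for _, s in self.removed)


def clean_fasta(
    assembly: Mapping[str, str],
    records: Sequence[ActionRecord],
    min_len: int | None = None,
) -> CleanResult:
    """Apply corrective actions to an assembly.

    EXCLUDE drops the sequence, TRIM removes the terminal span, FIX
    excises the internal span and splits the remainder into ``.1``,
    ``.2``, ... parts; review-class actions leave sequences untouched.
    The optional minimum-length filter runs last; sequences it drops go
    to the removed set so that kept + removed conserves every base.
    """
    by_seq: dict[str, list[ActionRecord]] = {}
    for rec in records:
        if rec.seq_id not in assembly:
            raise KeyError(f"action record references missing sequence {rec.seq_id!r}")
        if rec.end_pos > len(assembly[rec.seq_id]):
            raise ValueError(f"action span out of range on {rec.seq_id!r}")
        by_seq.setdefault(rec.seq_id, []).append(rec)
    result = CleanResult(kept={}, removed=[])
    for sid, seq in assembly.items():
        recs = by_seq.get(sid, [])
        excl = [r for r in recs if r.action == "EXCLUDE"]
        cuts = sorted(
            (r.start_pos - 1, r.end_pos, r.action)
            for r in recs
            if r.action in ("TRIM", "FIX")
        )
        if excl:
            r = excl[0]
            result.removed.append((f"{sid} 1..{len(seq)} EXCLUDE {r.division}", seq))
            result.n_excluded += 1
            continue
        if not cuts:
            result.kept[sid] = seq
            continue
        pieces: list[tuple[int, int]] = []
        prev = 0
        for a, b, action in cuts:
            if a > prev:
                pieces.append((prev, a))
            result.removed.append((f"{sid} {a + 1}..{b} {action}", seq[a:b]))
            if action == "TRIM":
                result.n_trimmed += 1
            else:
                result.n_fixed += 1
            prev = max(prev, b)
        if prev < len(seq):
            pieces.append((prev, len(seq)))
        if len(pieces) == 1:
            result.kept[sid] = seq[pieces[0][0] : pieces[0][1]]
        else:
            for i, (a, b) in enumerate(pieces, 1):
                result.kept[f"{sid}.{i}"] = seq[a:b]
    if min_len is not None:
        short = [sid for sid, s in result.kept.items() if len(s) < min_len]
        for sid in short:
            result.removed.append((f"{sid} MIN_LENGTH<{min_len}", result.kept.pop(sid)))
            result.n_dropped_short += 1
    result.total_removed_bp = result.removed_bp
    return result


# ------------------------------------------------------------- report


REPORT_COLUMNS = (
    "seq_id",
    "start_pos",
    "end_pos",
    "seq_length",
    "action",
    "contaminant_division",
    "top_tax_id",
    "coverage_len",
    "score",
)


def write_action_report(records: Sequence[ActionRecord], path: str | Path) -> None:
    recs = sorted(records, key=lambda r: (r.seq_id, r.start_pos, r.end_pos))
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(REPORT_COLUMNS) + "\n")
        for r in recs:
            fh.write(
                f"{r.seq_id}\t{r.start_pos}\t{r.end_pos}\t{r.seq_length}\t"
                f"{r.action}\t{r.division}\t{r.top_tax_id}\t{r.coverage_len}\t"
                f"{r.score:g}\n"
            )


def parse_action_report(path: str | Path) -> list[ActionRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            records.append(
                ActionRecord(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4], f[5],
                    int(f[6]), int(f[7]), float(f[8]),
                )
            )
    return records


def bin_contaminants(result: CleanResult, path: str | Path) -> None:
    """Write removed sequence (whole contigs and excised spans) to a
    FASTA with provenance deflines for further review."""
    with open(path, "w") as fh:
        for defline, seq in result.removed:
            fh.write(f">{defline}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in records.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
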