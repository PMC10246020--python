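"""Sensitivity / specificity evaluation on fragmented genomes.

The protocol fragments a genome into fixed-size windows (1 / 10 /
100 kbp) and runs the screen twice: once with a deliberately *false*
tax-id from a different kingdom (sensitivity — every fragment is a
known contaminant relative to the declared organism) and once with the
true tax-id (specificity — no fragment should be called). Repeat
masking is turned off for sensitivity runs. An optional species-dropout
mode excludes alignments to the source species' own tax-ids, emulating
detection of a novel organism absent from the database.

Sensitivity is the percentage of fragments receiving a corrective
action (EXCLUDE / TRIM / FIX) whose division matches the true source;
fragments assigned prokaryote virus count as true positives for
prokaryote sources. Specificity is the percentage of fragments with no
corrective or REVIEW action. Sequence-level specificity bounds over a
set of screened genomes:

    upper = 100 * (1 - same_kingdom_call_bp / (total_bp - cross_kingdom_call_bp))
    lower = 100 * (1 - all_call_bp / total_bp)
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .actions import CORRECTIVE
from .config import GxConfig
from .pipeline import ScreenResult, screen_assembly
from .refdb import ReferenceDB
from .taxonomy import PROKARYOTES

FN_CATEGORIES = (
    "review",
    "virus",
    "contaminant-inter-kingdom",
    "contaminant-intra-kingdom",
    "non-contaminant",
)


@dataclass
class EvalResult:
    fragment_size: int
    n_fragments: int
    sensitivity: float | None = None  # percent
    specificity: float | None = None  # percent
    false_negative_breakdown: dict[str, int] = field(default_factory=dict)
    result: ScreenResult | None = None

    def __post_init__(self):
        for v in (self.sensitivity, self.specificity):
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")


def _actions_by_seq(result: ScreenResult) -> dict[str, list]:
    by_seq: dict[str, list] = {}
    for rec in result.action_records:
        by_seq.setdefault(rec.seq_id, []).append(rec)
    return by_seq


def run_sensitivity_test(
    fragments: Mapping[str, str],
    db: ReferenceDB,
    discordant_tax_id: int,
    true_division: str,
    cfg: GxConfig | None = None,
    dropout_species: Iterable[int] = (),
) -> EvalResult:
    """Screen known-foreign fragments under a false tax-id and score
    corrective-action recovery of the true division."""
    cfg = (cfg or GxConfig()).replace(
        mask_transposons=False,
        exclude_tax_ids=frozenset(dropout_species),
    )
    result = screen_assembly(fragments, discordant_tax_id, db, cfg)
    taxonomy = db.taxonomy
    source_prok = taxonomy.kingdom_of_division(true_division) in PROKARYOTES
    by_seq = _actions_by_seq(result)
    tp = 0
    breakdown = {k: 0 for k in FN_CATEGORIES}
    for sid in fragments:
        recs = by_seq.get(sid, [])
        corrective = [r for r in recs if r.action in CORRECTIVE]
        reviews = [r for r in recs if r.action not in CORRECTIVE]
        if any(r.division == true_division for r in corrective):
            tp += 1
        elif source_prok and any(
            taxonomy.kingdom_of_division(r.division) == "Virus" for r in corrective
        ):
            tp += 1  # prokaryote-virus assignments count as true positives
        elif any(r.division == true_division for r in reviews):
            breakdown["review"] += 1
        elif any(
            taxonomy.kingdom_of_division(r.division) == "Virus" for r in corrective + reviews
        ):
            breakdown["virus"] += 1
        elif corrective:
            true_kingdom = taxonomy.kingdom_of_division(true_division)
            wrong = corrective[0]
            if taxonomy.kingdom_of_division(wrong.division) == true_kingdom:
                breakdown["contaminant-intra-kingdom"] += 1
            else:
                breakdown["contaminant-inter-kingdom"] += 1
        else:
            breakdown["non-contaminant"] += 1
    n = len(fragments)
    sizes = {len(s) for s in fragments.values()}
    return EvalResult(
        fragment_size=max(sizes) if sizes else 0,
        n_fragments=n,
        sensitivity=100.0 * tp / n if n else 0.0,
        false_negative_breakdown=breakdown,
        result=result,
    )


def run_specificity_test(
    fragments: Mapping[str, str],
    db: ReferenceDB,
    true_tax_id: int,
    cfg: GxConfig | None = None,
    dropout_species: Iterable[int] = (),
) -> EvalResult:
    """Screen a clean genome under its true tax-id; specificity counts
    fragments free of corrective *and* REVIEW actions."""
    cfg = (cfg or GxConfig()).replace(exclude_tax_ids=frozenset(dropout_species))
    result = screen_assembly(fragments, true_tax_id, db, cfg)
    flagged = {
        rec.seq_id
        for rec in result.action_records
        if rec.action in CORRECTIVE or rec.action == "REVIEW"
    }
    n = len(fragments)
    sizes = {len(s) for s in fragments.values()}
    return EvalResult(
        fragment_size=max(sizes) if sizes else 0,
        n_fragments=n,
        specificity=100.0 * (n - len(flagged)) / n if n else 100.0,
        result=result,
    )


def sequence_level_specificity_bounds(
    calls: Sequence[tuple[int, bool]], total_genome_bp: int
) -> tuple[float, float]:
    """Upper and lower sequence-level specificity bounds.

    ``calls`` holds (length, is_same_kingdom) for every contaminant
    call across all screened genomes; ``total_genome_bp`` is the summed
    genome length. Same-kingdom calls are ambiguous (could be real
    sequence), so the upper bound discounts only them, measured against
    the genome length with confirmed cross-kingdom contaminants
    removed; the lower bound treats every call as a false positive.
    """
    if total_genome_bp <= 0:
        raise ValueError("total genome length must be positive")
    same = sum(length for length, same_k in calls if same_k)
    cross = sum(length for length, same_k in calls if not same_k)
    upper = 100.0 * (1.0 - same / (total_genome_bp - cross))
    lower = 100.0 * (1.0 - (same + cross) / total_genome_bp)
    return upper, lower
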