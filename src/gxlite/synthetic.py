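"""Synthetic multi-taxon fixtures with controlled divergence.

Root genomes are i.i.d. uniform ACGT; descendant genomes are derived by
transition-biased substitutions (default ts:tv = 2, the genome-wide
norm for most organisms) plus optional small indels, giving a reference
set with known inter-genome divergences. Contaminated assemblies are
assembled from a host genome plus planted contaminants of four
archetypes — whole-contig, terminal chimera, internal chimera, and
"novel species" (a diverged relative of a database entry) — with exact
ground-truth intervals.

Everything is deterministic under the supplied seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import decode, encode, random_codes
from .taxonomy import TaxNode, Taxonomy

DEFAULT_TS_TV = 2.0


@dataclass
class SimTaxon:
    """One simulated species and its genome derivation."""

    tax_id: int
    division: str
    kingdom: str
    genome_length: int
    parent_source: int | None = None  # tax_id whose genome is mutated; None = root
    divergence: float = 0.0  # substitution fraction vs parent_source
    ts_tv: float = DEFAULT_TS_TV
    indel_rate: float = 0.0  # indel events per bp

    def __post_init__(self):
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be within [0, 0.3]")
        if self.ts_tv <= 0:
            raise ValueError("ts/tv ratio must be positive")


def mutate_codes(
    codes: np.ndarray,
    divergence: float,
    ts_tv: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
    indel_max: int = 5,
) -> np.ndarray:
    """Transition-biased substitutions plus small random indels.

    Substitution sites are i.i.d. at rate ``divergence``; each is a
    transition with probability ts_tv / (ts_tv + 1), else one of the
    two transversions. In code space (A=0, C=1, G=2, T=3) a transition
    is ``code ^ 2`` and the transversions are ``code ^ 1`` / ``code ^ 3``.
    """
    out = codes.copy()
    n = len(out)
    sites = np.flatnonzero(rng.random(n) < divergence)
    if len(sites):
        is_ts = rng.random(len(sites)) < ts_tv / (ts_tv + 1.0)
        out[sites[is_ts]] ^= 2
        tv = sites[~is_ts]
        out[tv] ^= np.where(rng.random(len(tv)) < 0.5, 1, 3).astype(np.uint8)
    if indel_rate > 0:
        events = np.sort(rng.choice(n, size=rng.poisson(indel_rate * n), replace=False))
        pieces = []
        prev = 0
        for pos in events:
            pieces.append(out[prev:pos])
            size = int(rng.integers(1, indel_max + 1))
            if rng.random() < 0.5:
                pieces.append(random_codes(rng, size))  # insertion
                prev = pos
            else:
                prev = min(n, pos + size)  # deletion
        pieces.append(out[prev:])
        out = np.concatenate(pieces)
    return out


@dataclass
class ReferenceSet:
    taxonomy: Taxonomy
    genomes: dict[int, np.ndarray]  # tax_id -> code array
    records: dict[str, str]  # subject_id -> sequence
    tax_map: dict[str, int]  # subject_id -> tax_id

    def subject_id(self, tax_id: int) -> str:
        return f"tax{tax_id}_g1"


def simulate_reference_set(
    seed: int, taxa: Sequence[SimTaxon]
) -> ReferenceSet:
    """Generate genomes for a taxon list and the matching taxonomy.

    Kingdom and division nodes are synthesized automatically; each
    taxon contributes one genome sequence named ``tax<ID>_g1``.
    """
    rng = np.random.default_rng(seed)
    genomes: dict[int, np.ndarray] = {}
    for t in taxa:
        if t.parent_source is None:
            genomes[t.tax_id] = random_codes(rng, t.genome_length)
        else:
            parent = genomes[t.parent_source]
            g = mutate_codes(parent, t.divergence, t.ts_tv, rng, t.indel_rate)
            genomes[t.tax_id] = g[: t.genome_length] if t.genome_length else g
    nodes = [TaxNode(1, 1, "no-rank", "unclassified", "Synthetic")]
    kingdom_ids: dict[str, int] = {}
    division_ids: dict[str, int] = {}
    for t in taxa:
        if t.kingdom not in kingdom_ids:
            kid = 10 + len(kingdom_ids)
            kingdom_ids[t.kingdom] = kid
            nodes.append(TaxNode(kid, 1, "kingdom", t.kingdom, t.kingdom))
        if t.division not in division_ids:
            did = 100 + len(division_ids)
            division_ids[t.division] = did
            nodes.append(
                TaxNode(did, kingdom_ids[t.kingdom], "division", t.division, t.kingdom)
            )
        nodes.append(
            TaxNode(t.tax_id, division_ids[t.division], "species", t.division, t.kingdom)
        )
    taxonomy = Taxonomy(nodes)
    records = {f"tax{t.tax_id}_g1": decode(genomes[t.tax_id]) for t in taxa}
    tax_map = {f"tax{t.tax_id}_g1": t.tax_id for t in taxa}
    return ReferenceSet(taxonomy, genomes, records, tax_map)


def default_reference_taxa() -> list[SimTaxon]:
    """The stock study conditions: 13 taxa over 5 kingdoms.

    Sized so a full build-plus-screen cycle runs in minutes on one CPU
    while exercising every code path: a bacterial host clade with a
    5%-diverged sibling (novel-species tests), a second bacterial
    division (rare prok-in-prok contamination), a well-represented
    metazoan decoy division of five species (discordant tax-id tests),
    a eukaryote host, and plant / fungal / viral contaminant sources.
    """
    return [
        # Bacteria — host clade (gamma) and a second division (alpha)
        SimTaxon(1001, "gamma-proteobacteria", "Bacteria", 300_000),
        SimTaxon(1002, "gamma-proteobacteria", "Bacteria", 0, 1001, 0.05, indel_rate=2e-4),
        SimTaxon(1003, "gamma-proteobacteria", "Bacteria", 200_000),
        SimTaxon(1011, "alpha-proteobacteria", "Bacteria", 150_000),
        # Metazoa — decoy division with five species (well-represented)
        SimTaxon(2001, "primates", "Metazoa", 40_000),
        SimTaxon(2002, "primates", "Metazoa", 0, 2001, 0.08, indel_rate=2e-4),
        SimTaxon(2003, "primates", "Metazoa", 30_000),
        SimTaxon(2004, "primates", "Metazoa", 30_000),
        SimTaxon(2005, "primates", "Metazoa", 30_000),
        # Metazoa — eukaryote host division
        SimTaxon(2101, "insects", "Metazoa", 250_000),
        # other kingdoms
        SimTaxon(3001, "monocots", "Viridiplantae", 120_000),
        SimTaxon(4001, "ascomycetes", "Fungi", 120_000),
        SimTaxon(5001, "prok-viruses", "Virus", 30_000),
    ]


@dataclass
class ContaminantSpec:
    """One planted contaminant.

    kind: 'whole_contig' | 'terminal' | 'internal'. ``divergence`` > 0
    plants a *novel species*: a mutated copy of the source genome slice
    rather than an exact one. ``spacer`` inserts a 10 N joint at the
    chimera junction (splitting it into contigs downstream); without it
    the chimera must be found intra-contig.
    """

    kind: str
    source_tax: int
    length: int
    divergence: float = 0.0
    ts_tv: float = DEFAULT_TS_TV
    spacer: bool = False


@dataclass
class TruthInterval:
    seq_id: str
    start: int  # 0-based half-open, contaminant bases only
    end: int
    source_tax: int
    kind: str


def make_contaminated_assembly(
    host_records: dict[str, str],
    specs: Sequence[ContaminantSpec],
    ref: ReferenceSet,
    seed: int,
) -> tuple[dict[str, str], list[TruthInterval]]:
    """Plant contaminants into a host assembly; returns the assembly
    and exact truth intervals (BED-style, 0-based half-open)."""
    rng = np.random.default_rng(seed)
    assembly = dict(host_records)
    truth: list[TruthInterval] = []
    host_ids = sorted(host_records)
    for i, spec in enumerate(specs):
        src = ref.genomes[spec.source_tax]
        if spec.length > len(src):
            raise ValueError(f"contaminant longer than source genome: {spec}")
        off = int(rng.integers(0, len(src) - spec.length + 1))
        frag = src[off : off + spec.length].copy()
        if spec.divergence > 0:
            frag = mutate_codes(frag, spec.divergence, spec.ts_tv, rng)
        frag_seq = decode(frag)
        joint = "N" * 10 if spec.spacer else ""
        if spec.kind == "whole_contig":
            sid = f"contam_{i}_tax{spec.source_tax}"
            assembly[sid] = frag_seq
            truth.append(TruthInterval(sid, 0, len(frag_seq), spec.source_tax, spec.kind))
        elif spec.kind == "terminal":
            hid = host_ids[int(rng.integers(0, len(host_ids)))]
            base = assembly[hid]
            start = len(base) + len(joint)
            assembly[hid] = base + joint + frag_seq
            truth.append(
                TruthInterval(hid, start, start + len(frag_seq), spec.source_tax, spec.kind)
            )
        elif spec.kind == "internal":
            hid = host_ids[int(rng.integers(0, len(host_ids)))]
            base = assembly[hid]
            mid = len(base) // 2
            start = mid + len(joint)
            assembly[hid] = base[:mid] + joint + frag_seq + joint + base[mid:]
            truth.append(
                TruthInterval(hid, start, start + len(frag_seq), spec.source_tax, spec.kind)
            )
        else:
            raise ValueError(f"unknown contaminant kind {spec.kind!r}")
    return assembly, truth


def fragment_genome(
    records: dict[str, str], window: int
) -> dict[str, str]:
    """Split every record into consecutive non-overlapping windows; the
    terminal remainder is retained as a final (shorter) fragment."""
    out: dict[str, str] = {}
    for rid, seq in records.items():
        for a in range(0, len(seq), window):
            b = min(a + window, len(seq))
            out[f"{rid}:{a}-{b}"] = seq[a:b]
    return out


def write_truth_bed(truth: Sequence[TruthInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.seq_id}\t{t.start}\t{t.end}\ttax{t.source_tax}_{t.kind}\n")
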