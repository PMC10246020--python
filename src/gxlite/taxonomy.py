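"""NCBI-style taxonomy table: tax-ids, divisions, and kingdom groupings.

Species tax-ids are categorized into taxonomic divisions, and divisions
roll up into broader kingdoms: Metazoa (animals), Viridiplantae
(plants), Fungi, other-Eukaryota (protists), Bacteria, Archaea, plus
Virus and Synthetic for common contaminant sources.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

KINGDOMS = frozenset(
    {
        "Metazoa",
        "Viridiplantae",
        "Fungi",
        "other-Eukaryota",
        "Bacteria",
        "Archaea",
        "Virus",
        "Synthetic",
    }
)

#: kingdoms whose genomes are indexed at the dense (10 bp) stride and are
#: exempt from transposon masking
PROKARYOTE_LIKE = frozenset({"Bacteria", "Archaea", "Virus", "Synthetic"})

#: kingdoms counted as prokaryote for the rare-contamination report gate
PROKARYOTES = frozenset({"Bacteria", "Archaea"})


@dataclass(frozen=True)
class TaxNode:
    tax_id: int
    parent_id: int
    rank: str
    division: str
    kingdom: str


class Taxonomy:
    """In-memory taxonomy table with division/kingdom lookups.

    Invariants checked at construction: every non-root node has a parent
    in the table; each division maps to exactly one kingdom.
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[int, TaxNode] = {n.tax_id: n for n in nodes}
        div_kingdom: dict[str, str] = {}
        for n in self.nodes.values():
            if n.kingdom not in KINGDOMS:
                raise ValueError(f"unknown kingdom {n.kingdom!r} for tax {n.tax_id}")
            if n.tax_id != n.parent_id and n.parent_id not in self.nodes:
                raise ValueError(
                    f"tax {n.tax_id} has parent {n.parent_id} absent from the table"
                )
            prev = div_kingdom.setdefault(n.division, n.kingdom)
            if prev != n.kingdom:
                raise ValueError(
                    f"division {n.division!r} maps to both {prev} and {n.kingdom}"
                )
        self._div_kingdom = div_kingdom

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def division(self, tax_id: int) -> str:
        return self.nodes[tax_id].division

    def kingdom(self, tax_id: int) -> str:
        return self.nodes[tax_id].kingdom

    def kingdom_of_division(self, division: str) -> str:
        return self._div_kingdom[division]

    def species_count_per_division(self) -> dict[str, int]:
        """Number of species-rank tax-ids per division (database
        representation, used by the declared-taxon sanity check)."""
        counts: dict[str, int] = {}
        for n in self.nodes.values():
            if n.rank == "species":
                counts[n.division] = counts.get(n.division, 0) + 1
        return counts

    # ----- I/O ------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t", dtype={"tax_id": int, "parent_id": int})
        required = {"tax_id", "parent_id", "rank", "division", "kingdom"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
        return cls(
            TaxNode(int(r.tax_id), int(r.parent_id), r.rank, r.division, r.kingdom)
            for r in df.itertuples()
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (n.tax_id, n.parent_id, n.rank, n.division, n.kingdom)
            for n in sorted(self.nodes.values(), key=lambda n: n.tax_id)
        ]
        pd.DataFrame(
            rows, columns=["tax_id", "parent_id", "rank", "division", "kingdom"]
        ).to_csv(path, sep="\t", index=False)


def read_seq_tax_map(path: str | Path) -> dict[str, int]:
    """Sequence-id -> tax-id map from a two-column TSV (seq_id, tax_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "tax_id": int})
    if not {"seq_id", "tax_id"} <= set(df.columns):
        raise ValueError("tax map must have columns seq_id, tax_id")
    return dict(zip(df.seq_id, df.tax_id))


def write_seq_tax_map(mapping: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["seq_id", "tax_id"]
    ).to_csv(path, sep="\t", index=False)
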