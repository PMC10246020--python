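"""Run configuration: every tunable threshold with its default.

The thresholds marked "stand-in" below are parts of the procedure whose
published description fixes the mechanism but not the constant; they
are deliberate package-level defaults and are all overridable from the
CLI or a config file (JSON round-trip via ``to_file``/``from_file``).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class GxConfig:
    # --- masking -----------------------------------------------------
    mask_low_complexity: bool = True
    mask_transposons: bool = True
    dust_window: int = 50  # bp sliding window for hexamer entropy
    dust_threshold: float = 4.5  # bits
    transposon_min_count: int = 8  # stand-in overrepresentation floor
    transposon_fold: float = 10.0  # stand-in: count >= fold * expected

    # --- seeding / alignment ----------------------------------------
    diag_tol: int = 1_000  # seed noise filter, diagonal
    antidiag_tol: int = 10_000  # seed noise filter, antidiagonal
    xdrop: int = 20  # stand-in ungapped extension drop-off
    sig_run: int = 16  # stand-in: exact run required of a continuation
    sig_window: int = 30  # stand-in: columns searched for that run
    indel_radius: int = 10  # stand-in gapped-extension offset search
    min_segment_score: float = 20.0  # stand-in noise floor on segments
    neighborhood_cap: int = 100_000  # pass-2 subject neighborhood limit

    # --- classification ---------------------------------------------
    min_coverage_cutoff: float = 0.10  # stand-in aggregate-coverage gate
    concordance_high: float = 0.75  # stand-in primary-set overlap, rich genomes
    concordance_low: float = 0.40  # stand-in floor for poorly covered genomes
    concordance_cov_high: float = 0.50  # aggregate coverage at which high applies
    concordance_cov_low: float = 0.05  # aggregate coverage at which low applies
    min_contam_cov_frac: float = 0.20  # stand-in per-sequence foreign coverage
    contam_score_ratio: float = 2.0  # stand-in foreign/primary score factor
    min_chimera_span: int = 2_000  # stand-in minimum foreign-exclusive span
    max_primary_overlap_frac: float = 0.5  # chimeric span may overlap primary this much
    well_represented_min_species: int = 5  # stand-in declared-taxon check
    declared_poor_abs: float = 0.02  # declared division coverage below this ...
    declared_poor_rel: float = 0.25  # ... or below this fraction of aggregate

    # --- actions -----------------------------------------------------
    exclude_cov_frac: float = 0.80  # stand-in "high contaminant coverage"
    trim_end_slack: int = 100  # span within this of an end -> TRIM not FIX
    same_kingdom_chimera_min: int = 10_000  # chimera span gate, same kingdom
    rare_prok_frac: float = 0.01  # prok-in-prok REVIEW_RARE gate
    lgt_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("alpha-proteobacteria", "Metazoa")]
    )  # (contaminant division, host kingdom) known-integrant pairs -> INFO
    min_len: int | None = None  # optional post-cleaning length filter

    # --- evaluation / misc -------------------------------------------
    exclude_tax_ids: frozenset[int] = field(default_factory=frozenset)

    def replace(self, **kw) -> "GxConfig":
        return dataclasses.replace(self, **kw)

    # ----- plain-text round-trip ------------------------------------

    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["exclude_tax_ids"] = sorted(self.exclude_tax_ids)
        d["lgt_pairs"] = [list(p) for p in self.lgt_pairs]
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "GxConfig":
        d = json.loads(Path(path).read_text())
        d["exclude_tax_ids"] = frozenset(d.get("exclude_tax_ids", []))
        d["lgt_pairs"] = [tuple(p) for p in d.get("lgt_pairs", [])]
        return cls(**d)
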