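"""Action assignment gates, cleaning conservation, report round-trip."""
import pytest

from gxlite.actions import (
    ActionRecord,
    assign_action,
    bin_contaminants,
    clean_fasta,
    compute_genome_totals,
    parse_action_report,
    write_action_report,
)
from gxlite.classify import GenomeContext, HitEntry, SequenceCall
from gxlite.config import GxConfig
from gxlite.taxonomy import TaxNode, Taxonomy
from conftest import random_dna

cfg = GxConfig()


@pytest.fixture(scope="module")
def taxonomy():
    return Taxonomy(
        [
            TaxNode(1, 1, "no-rank", "unclassified", "Synthetic"),
            TaxNode(10, 1, "kingdom", "Bacteria", "Bacteria"),
            TaxNode(11, 1, "kingdom", "Metazoa", "Metazoa"),
            TaxNode(100, 10, "division", "gamma-proteobacteria", "Bacteria"),
            TaxNode(110, 10, "division", "alpha-proteobacteria", "Bacteria"),
            TaxNode(120, 11, "division", "insects", "Metazoa"),
            TaxNode(130, 11, "division", "primates", "Metazoa"),
            TaxNode(1000, 100, "species", "gamma-proteobacteria", "Bacteria"),
            TaxNode(1100, 110, "species", "alpha-proteobacteria", "Bacteria"),
            TaxNode(1200, 120, "species", "insects", "Metazoa"),
            TaxNode(1300, 130, "species", "primates", "Metazoa"),
        ]
    )


def hit(tax, division, kingdom, cov, score):
    return HitEntry(tax, division, kingdom, cov, score, [(0, cov)])


def contaminant_call(seq_id, length, division, spans, tax, kingdom):
    cov = sum(b - a for a, b in spans)
    c = SequenceCall(seq_id, length, "contaminant", division, list(spans))
    c.top_hit = HitEntry(tax, division, kingdom, cov, float(cov) * 0.9, list(spans))
    return c


def ctx_for(declared_tax, taxonomy, primary=None, agg=0.9):
    division = taxonomy.division(declared_tax)
    return GenomeContext(
        declared_tax, division, taxonomy.kingdom(declared_tax),
        primary or {division}, agg, cfg.min_coverage_cutoff,
    )


class TestAssignAction:
    def test_whole_sequence_cross_kingdom_exclude(self, taxonomy):
        """A fully foreign 20 kb contig in a cross-kingdom direction
        yields one EXCLUDE record spanning 1..20000."""
        ctx = ctx_for(1200, taxonomy)  # insect host
        call = contaminant_call("c", 20_000, "gamma-proteobacteria",
                                [(0, 20_000)], 1000, "Bacteria")
        totals = compute_genome_totals([call], ctx, taxonomy, 1_000_000)
        recs = assign_action(call, ctx, totals, taxonomy, cfg)
        assert [(r.action, r.start_pos, r.end_pos) for r in recs] == [
            ("EXCLUDE", 1, 20_000)
        ]

    def test_prok_in_prok_below_one_percent_review_rare(self, taxonomy):
        """Prok contaminant contigs summing to 0.5% of a prok assembly
        are REVIEW_RARE, not cleaned."""
        ctx = ctx_for(1000, taxonomy)
        calls = [
            contaminant_call(f"c{i}", 2500, "alpha-proteobacteria",
                             [(0, 2500)], 1100, "Bacteria")
            for i in range(2)
        ]
        totals = compute_genome_totals(calls, ctx, taxonomy, 1_000_000)
        assert totals.prok_in_prok_bp == 5000  # 0.5 %
        for call in calls:
            recs = assign_action(call, ctx, totals, taxonomy, cfg)
            assert [r.action for r in recs] == ["REVIEW_RARE"]

    def test_prok_in_prok_above_one_percent_cleaned(self, taxonomy):
        ctx = ctx_for(1000, taxonomy)
        calls = [
            contaminant_call(f"c{i}", 6000, "alpha-proteobacteria",
                             [(0, 6000)], 1100, "Bacteria")
            for i in range(2)
        ]
        totals = compute_genome_totals(calls, ctx, taxonomy, 1_000_000)
        assert totals.prok_in_prok_bp == 12_000  # 1.2 %
        recs = assign_action(calls[0], ctx, totals, taxonomy, cfg)
        assert [r.action for r in recs] == ["EXCLUDE"]

    def test_same_kingdom_chimera_below_10kb_suppressed(self, taxonomy):
        """An internal 8 kb same-kingdom foreign span in a metazoan
        sequence produces no chimera record."""
        ctx = ctx_for(1200, taxonomy)  # insects
        call = contaminant_call("s", 100_000, "primates",
                                [(40_000, 48_000)], 1300, "Metazoa")
        totals = compute_genome_totals([call], ctx, taxonomy, 1_000_000)
        assert assign_action(call, ctx, totals, taxonomy, cfg) == []

    def test_same_kingdom_chimera_at_10kb_review(self, taxonomy):
        ctx = ctx_for(1200, taxonomy)
        call = contaminant_call("s", 100_000, "primates",
                                [(40_000, 51_000)], 1300, "Metazoa")
        totals = compute_genome_totals([call], ctx, taxonomy, 1_000_000)
        recs = assign_action(call, ctx, totals, taxonomy, cfg)
        assert [r.action for r in recs] == ["REVIEW"]

    def test_cross_kingdom_terminal_trim_internal_fix(self, taxonomy):
        ctx = ctx_for(1200, taxonomy)
        terminal = contaminant_call("s", 100_000, "gamma-proteobacteria",
                                    [(92_000, 100_000)], 1000, "Bacteria")
        internal = contaminant_call("s2", 100_000, "gamma-proteobacteria",
                                    [(40_000, 48_000)], 1000, "Bacteria")
        totals = compute_genome_totals([terminal, internal], ctx, taxonomy, 10**6)
        assert [r.action for r in assign_action(terminal, ctx, totals, taxonomy, cfg)] == ["TRIM"]
        assert [r.action for r in assign_action(internal, ctx, totals, taxonomy, cfg)] == ["FIX"]

    def test_lgt_division_chimera_info(self, taxonomy):
        """An alphaproteobacterial integrant span in a metazoan host is
        INFO (endosymbiont LGT), not TRIM/FIX."""
        ctx = ctx_for(1200, taxonomy)
        call = contaminant_call("s", 100_000, "alpha-proteobacteria",
                                [(40_000, 55_000)], 1100, "Bacteria")
        totals = compute_genome_totals([call], ctx, taxonomy, 10**6)
        recs = assign_action(call, ctx, totals, taxonomy, cfg)
        assert [r.action for r in recs] == ["INFO"]

    def test_weak_foreign_with_genome_evidence_review(self, taxonomy):
        ctx = ctx_for(1200, taxonomy)
        strong = contaminant_call("a", 20_000, "gamma-proteobacteria",
                                  [(0, 20_000)], 1000, "Bacteria")
        weak = SequenceCall("b", 50_000, "inconclusive")
        weak.weak_foreign = hit(1000, "gamma-proteobacteria", "Bacteria", 3000, 150.0)
        weak.weak_spans = [(1000, 4000)]
        totals = compute_genome_totals([strong, weak], ctx, taxonomy, 10**6)
        recs = assign_action(weak, ctx, totals, taxonomy, cfg)
        assert [r.action for r in recs] == ["REVIEW"]
        # without genome-level evidence: nothing
        totals2 = compute_genome_totals([weak], ctx, taxonomy, 10**6)
        assert assign_action(weak, ctx, totals2, taxonomy, cfg) == []


class TestCleanFasta:
    def test_identity_when_no_records(self, rng):
        assembly = {"a": random_dna(rng, 1000), "b": random_dna(rng, 2000)}
        res = clean_fasta(assembly, [])
        assert res.kept == assembly and res.removed == []

    def test_fix_splits_and_conserves(self, rng):
        """FIX of span 4001..6000 in a 10 kb sequence leaves two 4 kb
        parts and removes exactly 2 kb."""
        seq = random_dna(rng, 10_000)
        rec = ActionRecord("s", 4001, 6000, 10_000, "FIX", "divX", 9, 2000, 100.0)
        res = clean_fasta({"s": seq}, [rec])
        assert sorted(res.kept) == ["s.1", "s.2"]
        assert len(res.kept["s.1"]) == len(res.kept["s.2"]) == 4000
        assert res.total_removed_bp == 2000
        assert res.kept["s.1"] + res.removed[0][1] + res.kept["s.2"] == seq

    def test_trim_removes_terminal_span(self, rng):
        seq = random_dna(rng, 10_000)
        rec = ActionRecord("s", 9001, 10_000, 10_000, "TRIM", "divX", 9, 1000, 80.0)
        res = clean_fasta({"s": seq}, [rec])
        assert res.kept == {"s": seq[:9000]}

    def test_exclude_drops_sequence(self, rng):
        seq = random_dna(rng, 3000)
        rec = ActionRecord("s", 1, 3000, 3000, "EXCLUDE", "divX", 9, 3000, 200.0)
        res = clean_fasta({"s": seq, "t": "ACGT" * 100}, [rec])
        assert "s" not in res.kept and "t" in res.kept

    def test_review_class_never_modifies(self, rng):
        assembly = {"s": random_dna(rng, 5000)}
        for action in ("REVIEW", "REVIEW_RARE", "INFO"):
            rec = ActionRecord("s", 1000, 2000, 5000, action, "divX", 9, 1000, 50.0)
            assert clean_fasta(assembly, [rec]).kept == assembly

    def test_min_len_filter(self, rng):
        """With a 1 kbp threshold, toy sequences {500, 999, 1000, 5000}
        keep exactly the two of length >= 1000."""
        assembly = {
            "a": random_dna(rng, 500),
            "b": random_dna(rng, 999),
            "c": random_dna(rng, 1000),
            "d": random_dna(rng, 5000),
        }
        res = clean_fasta(assembly, [], min_len=1000)
        assert sorted(res.kept) == ["c", "d"]
        assert res.kept_bp + res.removed_bp == 7499

    def test_conservation_random_fixtures(self, rng):
        """kept bp + removed bp == input bp exactly, across random
        record mixes."""
        for _ in range(10):
            assembly = {
                f"s{i}": random_dna(rng, int(rng.integers(1000, 20_000)))
                for i in range(5)
            }
            records = []
            for sid, seq in assembly.items():
                L = len(seq)
                r = rng.random()
                if r < 0.25:
                    records.append(ActionRecord(sid, 1, L, L, "EXCLUDE", "d", 9, L, 1.0))
                elif r < 0.5:
                    a = int(rng.integers(200, L - 200))
                    b = int(rng.integers(a, L - 100))
                    records.append(ActionRecord(sid, a, b, L, "FIX", "d", 9, b - a, 1.0))
                elif r < 0.7:
                    b = int(rng.integers(L // 2, L))
                    records.append(ActionRecord(sid, b, L, L, "TRIM", "d", 9, L - b, 1.0))
            res = clean_fasta(assembly, records, min_len=1000)
            total_in = sum(len(s) for s in assembly.values())
            assert res.kept_bp + res.removed_bp == total_in

    def test_missing_sequence_hard_error(self):
        rec = ActionRecord("ghost", 1, 10, 10, "EXCLUDE", "d", 9, 10, 1.0)
        with pytest.raises(KeyError):
            clean_fasta({"s": "ACGT"}, [rec])

    def test_out_of_range_span_hard_error(self):
        rec = ActionRecord("s", 1, 10, 10, "TRIM", "d", 9, 10, 1.0)
        with pytest.raises(ValueError):
            clean_fasta({"s": "ACGT"}, [rec])


class TestReportRoundTrip:
    def _records(self):
        return [
            ActionRecord("b", 1, 5000, 5000, "EXCLUDE", "divX", 7, 4800, 321.5),
            ActionRecord("a", 100, 900, 2000, "FIX", "divY", 8, 800, 55.0),
            ActionRecord("a", 1500, 1900, 2000, "REVIEW", "divY", 8, 400, 30.0),
        ]

    def test_empty_report_is_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_action_report([], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#seq_id")

    def test_sorted_and_roundtrips(self, tmp_path):
        p = tmp_path / "r.tsv"
        recs = self._records()
        write_action_report(recs, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 4
        parsed = parse_action_report(p)
        assert [(r.seq_id, r.start_pos) for r in parsed] == [
            ("a", 100), ("a", 1500), ("b", 1)
        ]
        assert sorted(map(vars, parsed), key=lambda d: (d["seq_id"], d["start_pos"])) == sorted(
            map(vars, recs), key=lambda d: (d["seq_id"], d["start_pos"])
        )


class TestBinContaminants:
    def test_empty_bin(self, tmp_path, rng):
        res = clean_fasta({"s": random_dna(rng, 1000)}, [])
        out = tmp_path / "bin.fa"
        bin_contaminants(res, out)
        assert out.read_text() == ""

    def test_excluded_sequence_binned_and_conserved(self, tmp_path, rng):
        seq = random_dna(rng, 20_000)
        rec = ActionRecord("s", 1, 20_000, 20_000, "EXCLUDE", "divX", 9, 20_000, 500.0)
        res = clean_fasta({"s": seq, "keep": random_dna(rng, 3000)}, [rec])
        out = tmp_path / "bin.fa"
        bin_contaminants(res, out)
        text = out.read_text()
        assert text.startswith(">s 1..20000 EXCLUDE")
        binned = "".join(l for l in text.splitlines() if not l.startswith(">"))
        assert binned == seq
        assert res.kept_bp + res.removed_bp == 23_000
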