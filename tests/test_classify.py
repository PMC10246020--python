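"""Evidence truncation, primary-division inference, declared-taxon
check, per-sequence calls."""
import pytest

from gxlite.aligner import AlignmentSegment
from gxlite.classify import (
    GenomeContext,
    HitEntry,
    SequenceEvidence,
    call_sequence,
    check_declared_taxon,
    infer_primary_divisions,
    summarize_hits,
)
from gxlite.config import GxConfig
from gxlite.taxonomy import TaxNode, Taxonomy


@pytest.fixture(scope="module")
def taxonomy():
    nodes = [
        TaxNode(1, 1, "no-rank", "unclassified", "Synthetic"),
        TaxNode(10, 1, "kingdom", "Bacteria", "Bacteria"),
        TaxNode(11, 1, "kingdom", "Metazoa", "Metazoa"),
        TaxNode(12, 1, "kingdom", "Fungi", "Fungi"),
    ]
    # divA/divB same kingdom (Bacteria), divC Metazoa, divD Fungi
    nodes += [
        TaxNode(100, 10, "division", "divA", "Bacteria"),
        TaxNode(110, 10, "division", "divB", "Bacteria"),
        TaxNode(120, 11, "division", "divC", "Metazoa"),
        TaxNode(130, 12, "division", "divD", "Fungi"),
    ]
    # species: divA rich (6 species), others small
    for i in range(6):
        nodes.append(TaxNode(1000 + i, 100, "species", "divA", "Bacteria"))
    nodes += [
        TaxNode(1100, 110, "species", "divB", "Bacteria"),
        TaxNode(1200, 120, "species", "divC", "Metazoa"),
        TaxNode(1300, 130, "species", "divD", "Fungi"),
    ]
    return Taxonomy(nodes)


def seg(tax, q0, q1, score, sid="sub"):
    return AlignmentSegment("q", q0, q1, sid, q0, q1, "+", [q1 - q0], score, tax)


cfg = GxConfig()


class TestSummarizeHits:
    def test_single_species(self, taxonomy):
        ev = summarize_hits("q", 10_000, [seg(1000, 0, 5000, 900)], taxonomy)
        assert [h.tax_id for h in ev.hits] == [1000]
        assert ev.hits[0].coverage_len == 5000

    def test_per_division_cap(self, taxonomy):
        """Five species, three in one division: the division keeps its
        best two; four species reported overall."""
        segs = [
            seg(1000, 0, 5000, 900),
            seg(1001, 0, 4500, 800),
            seg(1002, 0, 4000, 700),  # third divA species -> dropped
            seg(1100, 0, 3500, 600),
            seg(1200, 0, 3000, 500),
        ]
        ev = summarize_hits("q", 10_000, segs, taxonomy)
        assert len(ev.hits) == 4
        assert [h.tax_id for h in ev.hits] == [1000, 1001, 1100, 1200]

    def test_randomized_truncation_matches_oracle(self, taxonomy, rng):
        species = [1000, 1001, 1002, 1003, 1100, 1200, 1300]
        for _ in range(30):
            segs = []
            for t in species:
                if rng.random() < 0.3:
                    continue
                a = int(rng.integers(0, 5000))
                b = a + int(rng.integers(100, 4000))
                segs.append(seg(t, a, b, float(rng.integers(10, 1000))))
            ev = summarize_hits("q", 20_000, segs, taxonomy)
            # oracle: sort by (coverage, score), greedy with caps
            table = [
                (s.q_end - s.q_start, s.score, s.tax_id, taxonomy.division(s.tax_id))
                for s in segs
            ]
            table.sort(key=lambda r: (-r[0], -r[1], r[2]))
            kept, per_div = [], {}
            for cov, sc, t, d in table:
                if len(kept) >= 4 or per_div.get(d, 0) >= 2:
                    if per_div.get(d, 0) >= 2:
                        continue
                    break
                kept.append(t)
                per_div[d] = per_div.get(d, 0) + 1
            assert [h.tax_id for h in ev.hits] == kept


def make_evidence(taxonomy, per_seq):
    """per_seq: {seq_id: (length, [(tax, [(a,b),...], score), ...])}"""
    out = {}
    for sid, (length, hits) in per_seq.items():
        entries = []
        for tax, intervals, score in hits:
            cov = sum(b - a for a, b in intervals)
            entries.append(
                HitEntry(
                    tax, taxonomy.division(tax), taxonomy.kingdom(tax),
                    cov, score, sorted(intervals),
                )
            )
        entries.sort(key=lambda h: (-h.coverage_len, -h.score, h.tax_id))
        out[sid] = SequenceEvidence(sid, length, entries)
    return out


class TestInferPrimaryDivisions:
    def test_single_division(self, taxonomy):
        ev = make_evidence(
            taxonomy, {"s": (10_000, [(1000, [(0, 9000)], 900)])}
        )
        ctx = infer_primary_divisions(ev, 1000, taxonomy, cfg)
        assert ctx.primary_set == {"divA"}
        assert ctx.aggregate_coverage == pytest.approx(0.9)

    def test_same_kingdom_high_overlap_joins(self, taxonomy):
        """Two same-kingdom divisions with ~90% mutual overlap are both
        primary."""
        ev = make_evidence(
            taxonomy,
            {
                "s": (
                    10_000,
                    [
                        (1000, [(0, 9000)], 900),
                        (1100, [(500, 8600)], 700),
                    ],
                )
            },
        )
        ctx = infer_primary_divisions(ev, 1000, taxonomy, cfg)
        assert ctx.primary_set == {"divA", "divB"}

    def test_kingdom_gate_blocks_cross_kingdom(self, taxonomy):
        """A different-kingdom division is never primary, regardless of
        overlap."""
        ev = make_evidence(
            taxonomy,
            {
                "s": (
                    10_000,
                    [
                        (1000, [(0, 9000)], 900),
                        (1200, [(500, 8600)], 700),  # Metazoa
                    ],
                )
            },
        )
        ctx = infer_primary_divisions(ev, 1000, taxonomy, cfg)
        assert ctx.primary_set == {"divA"}

    def test_low_overlap_division_stays_out(self, taxonomy):
        ev = make_evidence(
            taxonomy,
            {
                "host": (50_000, [(1000, [(0, 45_000)], 2000)]),
                "cont": (10_000, [(1100, [(0, 9500)], 800)]),
            },
        )
        ctx = infer_primary_divisions(ev, 1000, taxonomy, cfg)
        assert ctx.primary_set == {"divA"}

    def test_no_alignments_flags_low_coverage(self, taxonomy):
        ev = make_evidence(taxonomy, {"s": (10_000, [])})
        ctx = infer_primary_divisions(ev, 1000, taxonomy, cfg)
        assert ctx.primary_set == {"divA"}
        assert ctx.low_coverage


class TestCheckDeclaredTaxon:
    def test_concordant_declaration_unchanged(self, taxonomy):
        ev = make_evidence(taxonomy, {"s": (10_000, [(1000, [(0, 9000)], 900)])})
        ctx = infer_primary_divisions(ev, 1000, taxonomy, cfg)
        ctx = check_declared_taxon(ctx, taxonomy, cfg)
        assert not ctx.swapped and ctx.warning is None

    def test_wrong_wellrepresented_taxid_swaps(self, taxonomy):
        """Assembly aligns to divB, declared divA (6 db species, zero
        coverage): computed primary becomes contaminant + warning."""
        ev = make_evidence(taxonomy, {"s": (10_000, [(1100, [(0, 9000)], 900)])})
        ctx = infer_primary_divisions(ev, 1000, taxonomy, cfg)
        ctx = check_declared_taxon(ctx, taxonomy, cfg)
        assert ctx.swapped
        assert ctx.warning is not None
        assert ctx.effective_primary_set == {"divA"}

    def test_rare_declared_taxon_no_swap(self, taxonomy):
        """divB has one db species (below the representation floor):
        no swap; declared division joins the primary set."""
        ev = make_evidence(taxonomy, {"s": (10_000, [(1000, [(0, 9000)], 900)])})
        ctx = infer_primary_divisions(ev, 1100, taxonomy, cfg)
        ctx = check_declared_taxon(ctx, taxonomy, cfg)
        assert not ctx.swapped
        assert "divB" in ctx.primary_set


class TestCallSequence:
    def _ctx(self, primary={"divA"}, agg=0.9):
        return GenomeContext(
            1000, "divA", "Bacteria", set(primary), agg, cfg.min_coverage_cutoff
        )

    def test_no_hits_inconclusive(self, taxonomy):
        ev = SequenceEvidence("s", 5000, [])
        assert call_sequence(ev, self._ctx(), cfg).category == "inconclusive"

    def test_foreign_kingdom_covered_is_contaminant(self, taxonomy):
        ev = make_evidence(
            taxonomy, {"s": (5000, [(1200, [(0, 4750)], 700)])}
        )["s"]
        call = call_sequence(ev, self._ctx(), cfg)
        assert call.category == "contaminant"
        assert call.call_division == "divC"
        assert call.contaminant_spans == [(0, 4750)]

    def test_primary_hits_only(self, taxonomy):
        ev = make_evidence(taxonomy, {"s": (5000, [(1000, [(0, 4000)], 700)])})["s"]
        assert call_sequence(ev, self._ctx(), cfg).category == "primary-division"

    def test_low_aggregate_coverage_suppresses_call(self, taxonomy):
        ev = make_evidence(taxonomy, {"s": (5000, [(1200, [(0, 4750)], 700)])})["s"]
        call = call_sequence(ev, self._ctx(agg=0.05), cfg)
        assert call.category == "inconclusive"
        assert call.weak_foreign is not None

    def test_partition_is_total(self, taxonomy, rng):
        """Every randomized evidence object lands in exactly one of the
        three categories."""
        ctx = self._ctx()
        for _ in range(50):
            hits = []
            for tax in (1000, 1100, 1200, 1300):
                if rng.random() < 0.5:
                    a = int(rng.integers(0, 2000))
                    b = a + int(rng.integers(50, 3000))
                    hits.append((tax, [(a, b)], float(rng.integers(1, 900))))
            ev = make_evidence(taxonomy, {"s": (5000, hits)})["s"]
            call = call_sequence(ev, ctx, cfg)
            assert call.category in {"primary-division", "contaminant", "inconclusive"}

    def test_monotonic_in_contaminant_coverage(self, taxonomy):
        """Growing the foreign division's coverage never flips a
        contaminant call back to primary."""
        ctx = self._ctx()
        last_contaminant = False
        for cov in range(500, 5000, 500):
            ev = make_evidence(
                taxonomy,
                {"s": (5000, [(1000, [(0, 600)], 200), (1200, [(0, cov)], 650)])},
            )["s"]
            call = call_sequence(ev, ctx, cfg)
            if last_contaminant:
                assert call.category == "contaminant"
            last_contaminant = call.category == "contaminant"
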