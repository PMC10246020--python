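# Methods

This note documents the model behind `gxlite`, the parameters that
matter, what the synthetic fixtures do and do not emulate, and the
numerical choices made where the design was genuinely open.

## The screening model

Contamination detection is framed as cross-species alignment followed
by taxonomic arbitration. The aligner must find homology across real
evolutionary distance (a novel contaminant species is usually *not* in
any database), which drives every design choice below toward tolerance
of substitutions — especially transitions, which outnumber
transversions roughly 2:1 in most genomes.

### H-mer index

A 56 bp window is reduced to a 38-bit key in three steps: drop
positions with 0-based index ≡ 2 (mod 3); collapse {A,G} → 0 and
{C,T} → 1; canonicalize over strands with min(h(w), h(rc(w))). The
dropped positions coincide with codon-wobble sites whenever the window
is in-frame coding sequence, and the one-bit alphabet absorbs all
transitions, so only transversions at the 38 retained positions (and
indels) can break a key. 38 bits are identity-hashed — the bit-string
is the key — which is exact and collision-free; a production system
sharding over hundreds of gigabases might prefer a narrower hash, but
at desk scale there is no reason to accept collisions.

Database strides (10 bp prokaryote / 20 bp eukaryote, anchored at
subject position 0) keep the index proportional to genome count rather
than genome size; query windows are enumerated at stride 1, so a
homologous region cannot be missed by phasing. Windows containing any
non-ACGT symbol are skipped deterministically rather than randomized.
The second-pass window is 29 bp, the smallest length whose retained
count is 20 (→ 20-bit keys), suiting an index built per query sequence
on the fly.

### Masking

Two repeat classes would otherwise dominate seed traffic:

* **Low complexity** — a 50 bp window slides at 1 bp; the Shannon
  entropy (base 2) of its 45 overlapping hexamers is compared with
  4.5 bits. The base and threshold are mutually consistent: 45 distinct
  hexamers give log2 45 ≈ 5.49 bits, so random sequence stays unmasked
  while homopolymers (0 bits) and short-period repeats (≤ ~3.3 bits for
  a dinucleotide) are masked. Natural-log entropy could never reach
  4.5 for 45 items, which fixes the base choice.
* **Transposons (eukaryote queries only)** — h-mers counted at the
  second-pass width over sequences of length ≥ min(100 kbp, assembly
  N80 before N-splitting); an h-mer is overrepresented at count
  ≥ max(8, 10 × expectation) under a uniform model over the 2^20 key
  space. The scope rule prevents a flood of short contaminant contigs
  (e.g. phiX or viral amplicons) from teaching the masker to hide the
  very contamination being screened for. Both constants are
  configuration (`transposon_min_count`, `transposon_fold`).

Masks are *soft*: masked windows never seed, but extensions may run
through them, so a genuine alignment flanking a repeat is not
truncated.

### Alignment

Pass 1 is ungapped: seeds surviving the diagonal/antidiagonal noise
filter (1 kbp / 10 kbp) are X-drop extended (match +1, mismatch −3,
drop-off 20). Per-taxon statistics — count, max, sum, and sum of
squares of ungapped alignment lengths — select the taxa (top three per
statistic, ties at third included) for pass 2, which re-aligns each
selected taxon's subject neighborhoods (capped at min(100 kbp,
2 × query length), centered on pass-1 footprints, merged when touching)
against the query's 20-bit index, now with gapped extension: at each
segment end, indel offsets −10…+10 are scored by the identity of the
next 30 columns; the best offset is accepted only if its continuation
contains an exact run ≥ 16 bp, else extension stops. The 16-in-30 rule
is the package's concrete reading of "significant ungapped
continuation": 16 exact bases occur by chance once per ~4^8 columns,
making runaway extension through unrelated sequence vanishingly
unlikely, while 10 %-divergent homologs still present such runs
frequently.

The segment score sqrt(Σ lᵢ²) over 100 %-identity run lengths has the
property that splitting any run strictly lowers the score
(√(a²+b²) < a+b), so scattered mismatches — the signature of genuine
divergence — are penalized more than clustered ones arising from
artifacts or multi-nucleotide mutations.

Chunked queries (100 kbp, 100 bp overlap) are merged after pass 1 by
fusing segments on the same (subject, strand) diagonal (±10 bp) with
abutting query ranges and recomputing identity runs over the fused
range, making results equivalent to whole-sequence alignment.

### Classification

Per sequence, species evidence is capped at four overall and two per
division; the second species of a division distinguishes genuine
contamination from a singleton contaminated database entry. Genome
context then arbitrates:

* **Inferred primary set** — divisions from the top-coverage division's
  kingdom join the primary set when their aligned intervals overlap the
  top division's above a concordance threshold: 75 % at aggregate
  coverage ≥ 50 %, relaxed linearly to 40 % at ≤ 5 % (poorly
  represented genomes legitimately scatter their best hits across
  related divisions). Crossing kingdoms into the primary set is never
  allowed.
* **Aggregate-coverage gate** — no contaminant is called unless the
  genome's aggregate coverage (aligned length of top-4 hits / genome
  size) reaches 10 % (`min_coverage_cutoff`); this restricts calls to
  genomes with usable database representation.
* **Declared-taxon check** — if the declared division has ≥ 5 database
  species (`well_represented_min_species`) yet covers almost none of
  the assembly (< max(2 %, 25 % of aggregate)), the computed primary
  divisions are reported as contaminants with a warning: the tax-id is
  likely wrong or the assembly overwhelmingly contaminated. A *poorly*
  represented declared division instead joins the primary set, keeping
  calls conservative.

A sequence becomes a contaminant by either of two routes: {foreign
division covers ≥ 20 % of the sequence and out-scores the best primary
hit 2:1} (whole-sequence route), or {≥ 2 kbp of the foreign span lies
outside primary-division coverage and primary alignments overlap at
most half of it} (chimeric route). The second route exists because a
fixed per-sequence coverage fraction can never fire for a bounded span
inside an arbitrarily long contig; judging the span locally is what
makes TRIM/FIX calls possible at all. Sub-threshold foreign evidence is
retained and surfaces as REVIEW when its division has a conclusive call
elsewhere in the genome.

### Actions

Span-level mapping, in precedence order: whole-sequence coverage ≥ 80 %
→ EXCLUDE; same-kingdom chimeric span < 10 kb → suppressed, ≥ 10 kb →
REVIEW; (contaminant division, host kingdom) on the known-LGT list →
INFO; prokaryote-in-prokaryote totaling < 1 % of assembly length
(computed before any cleaning) → REVIEW_RARE; remaining spans within
100 bp of an end → TRIM, else FIX. Cleaning applies only
EXCLUDE/TRIM/FIX; FIX splits remainders into `.1`, `.2`, … parts;
kept + binned bases always equal the input exactly, including sequences
dropped by the optional minimum-length filter (1 kbp recommended for
eukaryote assemblies). Report coordinates are 1-based inclusive, so a
record with (start, end) ≠ (1, length) denotes a chimeric range.

## Synthetic fixtures

`simulate_reference_set` builds genomes top-down: roots are i.i.d.
uniform ACGT; children apply i.i.d. substitutions at the requested
divergence with ts:tv = 2 plus small (≤ 5 bp) indels. The stock set has
13 taxa over five kingdoms, sized (30–300 kbp) so that a full
build-screen-evaluate cycle runs in minutes on one CPU while touching
every code path: a bacterial host clade with a 5 %-diverged sibling for
novel-species (dropout) tests, a second bacterial division for
prokaryote-in-prokaryote and LGT scenarios, a five-species metazoan
decoy division satisfying the well-represented rule for discordant
tax-id tests, a eukaryote host, and plant/fungal/viral sources.
Contaminated assemblies plant whole contigs, terminal/internal
chimeras (optionally joined by a 10 N spacer), and diverged
novel-species fragments, each with exact truth intervals.

What the fixtures do **not** emulate: real base composition and GC
skew, biological repeat families (transposons are planted as literal
copies), assembly artifacts (collapsed repeats, consensus errors),
conserved genes shared across kingdoms, and real taxonomic tree depth.
Passing tests therefore demonstrate the machinery — seeding through
cleaning — is correct under controlled divergence, not that the
thresholds are field-calibrated for real genomes; the stand-in
thresholds (all in `GxConfig`) would need tuning against curated
contamination sets before production use.

## Evaluation protocol

A genome is fragmented into non-overlapping windows (1/10/100 kbp;
terminal remainders retained). Sensitivity runs declare a false tax-id
from another kingdom with repeat masking off — every fragment is then a
known contaminant — and count fragments receiving corrective actions
(EXCLUDE/TRIM/FIX) with the true source division; virus assignments
count as true positives for prokaryote sources. Specificity runs
declare the true tax-id and count fragments free of corrective and
REVIEW actions. Dropout mode excludes the source species' tax-ids from
alignment, emulating a novel organism. Sequence-level specificity
bounds across genomes:

    upper = 100 · (1 − same_kingdom_bp / (total_bp − cross_kingdom_bp))
    lower = 100 · (1 − all_call_bp / total_bp)

`scripts/acceptance.py` runs this protocol at 10 kbp on the stock
fixtures (30 fragments of a 300 kbp bacterial genome; the scale is the
package's choice to keep a full from-scratch rebuild under a minute)
plus a three-contaminant assembly recovery, and reports only what it
measures at run time.

## Numerical and degenerate-input choices

* Ambiguity codes other than N behave as N for run-splitting and
  otherwise just produce unseedable windows; all-N sequences vanish at
  splitting and are logged.
* DUST windows with zero valid hexamers are masked; sequences shorter
  than one window are scanned with a window shrunk to their length.
* Tie-breaks are deterministic everywhere: top-coverage division by
  (coverage, name); evidence by (coverage, score, tax-id); indel offset
  by (identity, |δ|, δ); top-3 taxa include ties at the third value.
* The X-drop trio (+1/−3/20) tolerates ~20 % mismatches before
  surrender and stops within ~7 columns of a homology boundary in
  random sequence.
* Identical inputs yield byte-identical reports (no hidden RNG in the
  screen path; simulation is fully seeded).

## Known limitations

* Thresholds in the classification and action layers are package
  defaults, not published constants; they are exposed in `GxConfig` and
  the CLI precisely because they are the most likely thing a user needs
  to adjust.
* Discrimination below the division level is out of scope, as is
  integrating composition/read-depth evidence.
* The per-sequence chimeric route requires ≥ 2 kbp of foreign-exclusive
  span; shorter integrants (small HGT fragments) are not called.
* The second-pass neighborhood definition (centered on pass-1
  footprints, merged when touching) is a reasonable reconstruction; a
  different neighborhood policy would change coverage estimates only in
  repeat-dense regions.
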