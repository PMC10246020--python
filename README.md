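# gxlite

Desk-scale cross-species contamination screening for genome assemblies.

Foreign DNA — bacterial reads in an insect assembly, human sequence in a
fungus, a symbiont assembled alongside its host — routinely ends up in
submitted genomes. `gxlite` screens an assembly against a multi-kingdom
reference database, assigns each sequence a taxonomic division, and
produces a cleaned FASTA plus an action report, entirely on one CPU with
synthetic, ground-truthed fixtures standing in for terabase-scale
reference data.

## Method

**Transition-tolerant hashed k-mers (h-mers).** Reference sequences are
indexed by 56 bp windows in which every third base (the codon-wobble
position for in-frame coding sequence) is dropped and the remaining 38
bases are collapsed to a one-bit purine/pyrimidine alphabet
({A,G} → 0, {C,T} → 1). Transition substitutions — the majority of
cross-species differences — are invisible to the key. Keys are
canonicalized over strands by `minword`: min(h(w), h(revcomp(w))).
Windows are collected at a 10 bp stride for prokaryotes and 20 bp for
eukaryotes; 38-bit keys are identity-hashed (collision-free).

**Two-pass seed-and-extend alignment.** Queries are split on runs of
≥ 10 Ns, chunked to 100 kbp (100 bp overlap), and masked: low-complexity
sequence where hexamer Shannon entropy in a 50 bp window falls below
4.5 bits, and (eukaryotes only) transposon-like repeats detected as
overrepresented h-mers. Pass 1 looks every unmasked query window up in
the index; seeds (q, subject, s) survive only with a neighbor within
1 kbp on the diagonal and 10 kbp on the antidiagonal,

    |(q1−s1)−(q2−s2)| ≤ 1 kbp,   |(q1+s1)−(q2+s2)| ≤ 10 kbp,

and grow into ungapped extensions. Per sequence, the taxa in the top
three by any of {number of ungapped alignments, max length, summed
length, squared summed length} are re-aligned in pass 2: their subject
neighborhoods (≤ min(100 kbp, 2× query length)) against an on-the-fly
20-bit index of the query, with gapped extension. A segment scores

    score = sqrt(Σ lᵢ²)

over its maximal 100 %-identity run lengths lᵢ, so broadly distributed
mismatches (true taxonomic distance) cost more than the same number
clustered (typical of artifacts).

**Assignment and actions.** Per sequence, coverage and score are kept
for ≤ 4 species, ≤ 2 per division. Genome-wide, same-kingdom divisions
whose alignments overlap the top-coverage division's form the inferred
primary set; aggregate coverage (aligned length of top-4 hits / genome
size) gates contaminant calling for poorly represented species, and a
well-represented declared division with no support flips the report
(wrong tax-id warning). Each contaminant sequence or span receives one
of six actions: **EXCLUDE / TRIM / FIX** (cleaned automatically) or
**REVIEW / REVIEW_RARE / INFO** (reported only) — with a 10 kb floor on
same-kingdom chimera spans, a < 1 %-of-assembly gate that downgrades
rare prokaryote-in-prokaryote contamination to REVIEW_RARE, and a
known-LGT list (e.g. alphaproteobacterial integrants in invertebrates)
mapped to INFO.

## Worked example

Generate fixtures (13-taxon reference over 5 kingdoms; a bacterial host
assembly carrying a 20 kbp foreign contig and a 12 kbp internal plant
insert), build the database, screen, and clean:

```bash
gxlite simulate --seed 11 --out fixtures --host-len 80000 \
    --contaminants whole_contig:1011:20000,internal:3001:12000
gxlite build-db --fasta fixtures/reference.fa --tax-map fixtures/seq_tax.tsv \
    --taxonomy fixtures/taxonomy.tsv --out db
gxlite screen --fasta fixtures/assembly.fa --tax-id 1001 --db db \
    --out-report report.tsv --summary-json summary.json
gxlite clean --fasta fixtures/assembly.fa --report report.tsv \
    --out clean.fa --bin contam.fa
```

The screen prints (abridged):

```
"declared_division": "gamma-proteobacteria",
"aggregate_coverage": 1.0,
"n_contaminant_sequences": 2,
"contaminant_bp_removed_by_kingdom": { "Bacteria": 20000, "Viridiplantae": 11997 }
```

and the action report contains:

```
#seq_id           start_pos end_pos seq_length action  contaminant_division top_tax_id coverage_len score
contam_0_tax1011  1         20000   20000      EXCLUDE alpha-proteobacteria 1011       20000        20000
tax1001_g1        40001     51997   92000      FIX     monocots             3001       12002        12001
```

The foreign contig is dropped whole (EXCLUDE spanning its full 20 kbp);
the plant insert planted at 40,000–52,000 is excised to within a few bp
(FIX 40001–51997) and the host contig is split into two parts. Cleaning
reports `kept 2 sequences (80003 bp); removed 31997 bp` — kept plus
binned bases equal the input exactly.

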