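# Methods

## The conversion model

The converter treats GFF3 → EMBL as a pure vocabulary-and-layout problem.
A GFF3 document is a forest of features linked by ID/Parent; an EMBL entry
is a closed-vocabulary feature table plus metadata that GFF3 cannot carry.
The conversion therefore has three independent parts:

1. **Structure** — parse the GFF3 into per-sequence feature trees. Lines
   sharing an ID (within one seqid) are one discontinuous feature whose
   segments become a `join(...)` location; this applies to CDS and to any
   other multi-line feature alike. Children hang off their Parent; orphans
   are kept as roots with a warning; circular Parent chains are a hard error.
2. **Vocabulary** — every feature type, attribute tag and the source/score
   columns pass through the three JSON translation tables. Resolution order
   is: explicit rule (rename or remove) → identity fallback against the
   INSDC vocabulary (probed case-insensitively, canonical casing emitted) →
   skip with one warning per distinct term per run. Removal is per node,
   never per subtree: a dropped `region` container still yields its gene
   children. The tables are validated at load time so a typo in a target
   name fails before any conversion work, with a nearest-name suggestion.
3. **Layout** — entries render with the ENA pre-submission conventions:
   `XXX` accession placeholders, no DT lines and no dates anywhere (ENA
   assigns them; this also makes output byte-deterministic), FT keys at
   column 6 and qualifier text at column 22, 80-character wrapping (quoted
   values break at spaces, locations only after commas, unbroken tokens are
   hard-wrapped), SQ lines of six 10-residue groups with a right-justified
   cumulative count.

## Coordinates, strand, phase

GFF3 and the INSDC feature table both use 1-based inclusive coordinates, so
no coordinate arithmetic exists anywhere in the package (a dedicated test
asserts locations pass through unchanged). Strand `-` becomes a
`complement(...)` wrapper; `.` and `?` render unstranded, with a warning
when a coding feature is affected.

`codon_start` is the GFF3 phase of the **first translated** CDS segment
plus one — the genomic-leftmost segment on the forward strand, the
genomic-rightmost on the reverse. An absent phase is treated as 0 with a
warning. The phase recurrence along a spliced CDS is
`next = (3 − ((len_prev − phase_prev) mod 3)) mod 3`, walking segments in
translation order; the test suite checks the implementation against a
brute-force oracle that lays out every coding base in ribosome order and
walks codons, over the full strand × phase × input-ordering truth table.

Partial-end flags are stored in feature orientation (`partial5` = the
feature's own 5′ end) and attached to genomic bounds at render time, so
`<` always marks the lower and `>` the upper genomic coordinate; under
`complement(...)` the feature's 5′ partial therefore appears as `>` on the
upper bound. Single-base segments render `n..n`, never bare `n`; the
validator's parser accepts both.

## Locus tags

ENA requires a registered, submission-wide systematic gene identifier.
Top-level features are numbered in ascending genomic order across all
sequences (in FASTA order) without per-sequence resets:
`PREFIX_00001, PREFIX_00002, ...` (width 5, increment 1, both
parameters of `assign_locus_tags`). A feature already carrying a
`locus_tag` attribute keeps it verbatim and does not consume a counter
value; its transcript/CDS descendants inherit it. The tag attaches to
gene-level and transcript/CDS-level feature keys only.

## Metadata gating

Conversion refuses to start until the mandatory submission metadata is
complete: organism, project accession, description, locus_tag prefix, plus
topology / molecule type / data class / taxonomic division drawn from their
controlled sets. `check_metadata` reports every problem at once, each with
the CLI flag that fixes it — an exhaustive fail-fast report was chosen over
interactive prompting so the tool stays scriptable in pipelines.

## The definition tables

`embl_feature_keys.json` (52 keys with mandatory/optional qualifier sets)
and `embl_qualifiers.json` (98 qualifiers with value formats: `none`,
`quoted-text`, `unquoted-token`, `integer`) encode the INSDC feature-table
release this package targets; `scripts/build_definition_tables.py`
regenerates them and asserts the counts. The per-key qualifier sets are a
curated rendering of the feature-table definition: a common core (note,
db_xref, gene, locus_tag, inference, ...) plus key-specific entries
(e.g. `codon_start`/`translation` on CDS, `anticodon` on tRNA,
`ncRNA_class` mandatory on ncRNA, `organism`/`mol_type` mandatory on
source). Qualifier-placement findings are warnings, not errors: the
archive's validator has the final word, the converter reports but does not
block.

## The synthetic fixtures

The generator emulates the *dialects* of four annotation tools — which
feature-type terms appear at which level and which attribute tags they
carry (Maker's `_AED`-style extras and exon features; Prokka's single-exon
genes with locus_tag/product/inference; Augustus' bare `g1`/`g1.t1` IDs and
multi-line CDS without exon features; Eugene's UTR features and Dbxref
tags). Gene models have 1–4 exons of 120–300 bp separated by 40–100 bp
introns, both strands, coding length trimmed to whole codons, phases from
the recurrence above, and genes packed left-to-right with 200–500 bp gaps
(a packing that does not fit the requested sequence length is an error).
Defaults in the tests use 5-gene/20 kb and 50-gene/120 kb instances — large
enough to exercise joins, strands and wrapping, small enough that the whole
suite runs in seconds.

What the fixtures do **not** emulate: real tool output captured verbatim,
sequence–annotation consistency (the FASTA is uniform random A/C/G/T, so
CDS features do not translate to ORFs), overlapping genes, trans-splicing,
fragmented assemblies. Passing the end-to-end tests therefore demonstrates
structural and vocabulary correctness across dialects, not biological
validation of real annotations — for a real submission, run the archive's
own validator on the output as a final check.

## The structural validator

`validate_flat_file` is an independent re-reader of the emitted format: it
re-parses entries line by line (line length, line codes and their order,
FT column layout, location grammar via its own recursive-descent parser,
coordinate ranges against the declared length, SQ composition recomputed
from the sequence lines, source-feature presence and span, vocabulary
membership and qualifier placement). It shares the definition tables and
location parser with the writer but none of the rendering code, so a writer
defect cannot validate itself. Its scope is deliberately structural; it
does not re-implement the archive's semantic rules (taxonomy checks, CDS
translation, assembly-level constraints).

## Numerical and formatting choices

* Output is byte-deterministic: no timestamps (gzip output is written with
  a fixed mtime and empty embedded filename), no locale-dependent
  formatting, stable qualifier insertion order, features sorted by leftmost
  coordinate with a stable tie-break so a gene precedes its transcript.
* Warning deduplication is per distinct term per run, so a million-exon
  file warns once about an unknown term, not a million times.
* Duplicate (name, value) qualifier pairs on one feature are emitted once.
* `"` inside qualifier values is escaped by doubling, per flat-file
  convention.
* An empty or directive-only GFF3 converts to source-only entries; a
  document whose data lines all fail to parse is an error.

## Known limitations

* GFF2/GTF input is out of scope; so are between-base (`n^n+1`) and
  remote-entry (`accession:span`) locations.
* Partial-end inference from the annotation (e.g. a CDS missing a start
  codon) is not attempted; partial flags are available in the location API
  for callers that know better.
* The bundled default translation tables cover the common vocabulary of the
  four emulated tools; other tools may need user-supplied rules, which is
  by design — the mapping files are the tool's configuration surface.
* `convert` holds one sequence's entry in memory at a time but keeps all
  parsed features; very large annotations are bounded by feature count,
  not sequence length.
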