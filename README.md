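# gff2embl

Convert any annotation tool's GFF3 into EMBL flat files ready for genome
annotation submission to the European Nucleotide Archive (ENA).

## The problem

Genome annotation pipelines (Maker, Prokka, Augustus, Eugene, ...) emit GFF3,
but the INSDC archives do not accept GFF3 as a submission format. The
conversion is awkward because GFF3 is deliberately flexible: the feature-type
column may hold any of thousands of Sequence Ontology terms and the attribute
column any tag an author likes, while the INSDC feature table is a closed
vocabulary — 52 feature keys and 98 qualifiers, each with placement rules and
value formats. Every annotation tool speaks its own dialect, so a converter
hard-wired to one tool's vocabulary fails on the next tool's output.

`gff2embl` makes the vocabulary mapping itself the configuration. Three JSON
translation tables — feature types → feature keys, attribute tags →
qualifiers, and the source/score columns → qualifiers — drive the
conversion. Each rule can rename a term, drop it (`"remove": true`), or
decorate its values with a prefix/suffix; terms with no rule fall back to an
identity match against the INSDC vocabulary, and anything still unresolved
is skipped with a warning rather than aborting the run. Export the bundled
tables with `gff2embl expose-translations`, edit them, and pass them back —
no pre-processing of the GFF3 itself is ever needed.

The package is a library first (every step is an importable function; see
`examples/`) with a thin command-line layer on top.

## What it does

* **Tolerant GFF3 reading** — any dialect; ID/Parent hierarchies, multi-line
  features merged on shared IDs, embedded `##FASTA` blocks; malformed lines
  become warnings naming the line number (`--strict` promotes them to errors).
* **INSDC feature-table model** — the 52 feature keys with their
  mandatory/optional qualifiers and the 98 qualifiers with value formats,
  shipped as versioned JSON data files; the location algebra
  (`join`, `complement`, `<`/`>` partials) with a round-trip parser, and
  `codon_start` computed from the GFF3 phase of the first translated CDS
  segment (`codon_start = phase + 1`).
* **Flat-file writing** — ID/AC/PR/DE/KW/OS/OC/reference headers with the
  pre-submission `XXX` placeholders, the fixed-column FT table, the SQ block
  with base-composition counts, 80-character wrapping everywhere, and
  byte-deterministic output.
* **Pipeline** — metadata gating (missing mandatory metadata fails fast with
  the flag that fixes each gap), locus_tag assignment in genomic order across
  the whole submission, CDS joins, mRNA spans from exon children, and a
  conversion report whose accounting identity
  `written + skipped + removed = candidates` holds on every run.
* **Fixtures & validation** — a deterministic generator of synthetic
  GFF3+FASTA in four tool dialects, and a structural flat-file validator
  (line lengths, line-code order, FT column layout, location grammar,
  coordinate ranges, SQ composition, qualifier legality) used as the
  desk-scale stand-in for the archive's own validator. The README of the
  original archive toolchain applies for the real thing: run ENA's Java
  flat-file validator on the output before an actual submission.

## Worked example

```python
from gff2embl import EntryMetadata, convert, generate_annotation

meta = EntryMetadata(
    organism="Escherichia coli", strain="K-12",
    project_id="PRJEB14359",
    description="whole genome shotgun assembly",
    locus_tag_prefix="TEST", taxonomic_division="PRO",
    lineage=["Bacteria", "Pseudomonadota", "Gammaproteobacteria"],
)
gff3_text, fasta_text = generate_annotation("prokka", n_genes=5,
                                            seq_length=20000, seed=42)
flatfile, report = convert(gff3_text, fasta_text, meta=meta)
print(report.entries_written, report.features_written)
```

prints `1 16`: one entry for the single contig, and 16 features — the
mandatory `source` feature spanning the contig plus (gene, mRNA, CDS) for
each of the 5 genes. The flat file begins

```
ID   XXX; XXX; linear; genomic DNA; XXX; PRO; 20000 BP.
XX
AC   XXX;
...
FT   source          1..20000
FT                   /organism="Escherichia coli"
FT                   /mol_type="genomic DNA"
FT                   /strain="K-12"
FT   gene            complement(181..328)
FT                   /gene="yfgA"
FT                   /locus_tag="PROKKA_00001"
FT                   /note="source:Prokka"
```

— the `XXX` placeholders are what ENA expects before accessioning, the gene
kept its pre-assigned locus_tag from the GFF3, and the source column value
`Prokka` was mapped to a `note` qualifier with the `source:` prefix by the
bundled column table. `validate_flat_file(flatfile)` returns `[]`.

The same run from the shell:

```bash
gff2embl fixtures --flavour prokka --genes 5 --length 20000 --seed 42 --out tmp/
gff2embl convert tmp/prokka.gff3 tmp/prokka.fa \
    --species "Escherichia coli" --strain K-12 --project_id PRJEB14359 \
    --description "whole genome shotgun assembly" --locus_tag TEST \
    --division PRO -o genome.embl
gff2embl validate genome.embl
```

More narrative walk-throughs live in `examples/`.

## Mapping-table schema

Each table is a JSON object keyed by the GFF3-side term. Feature rules:
`{"target": "<feature key>"}` or `{"remove": true}`. Qualifier rules
additionally accept `"prefix"`/`"suffix"` (applied per value) and a list
target `{"target": ["q1", "q2"]}` to fan one tag into several qualifiers.
Targets are checked against the definition tables at load time; an illegal
name fails with a nearest-match suggestion. The bundled definition tables
(`embl_feature_keys.json`, `embl_qualifiers.json`) pin the 52-key/98-name
INSDC release the package targets and are regenerated by
`scripts/build_definition_tables.py`; a future INSDC release would be a new
versioned data file, not a silent edit.

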