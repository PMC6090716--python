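"""Structurally validate flat-file text and see how corruptions are flagged.

Converts a small synthetic annotation, confirms the output is clean, then
deletes the entry terminator and truncates a line-length rule to show the
validator naming each broken line. Error-severity violations are the ones
that make a file unsubmittable; warnings are advisory.
"""

from gff2embl import EntryMetadata, convert, generate_annotation, validate_flat_file

meta = EntryMetadata(
    organism="Candida intermedia",
    project_id="PRJEB14359",
    description="genome assembly",
    locus_tag_prefix="TEST",
    taxonomic_division="FUN",
    lineage=["Eukaryota", "Fungi", "Saccharomycetes"],
)

gff3_text, fasta_text = generate_annotation("maker", 3, 15000, seed=7)
flatfile, _ = convert(gff3_text, fasta_text, meta=meta)

print("violations on converted output:", len(validate_flat_file(flatfile)))

broken = flatfile.rsplit("//", 1)[0]  # drop the entry terminator
for violation in validate_flat_file(broken):
    print(f"{violation.severity}: line {violation.line_number} "
          f"[{violation.rule_id}] {violation.message}")

lines = flatfile.splitlines()
lines[0] = lines[0] + " " * 40  # push the ID line past 80 characters
for violation in validate_flat_file("\n".join(lines) + "\n"):
    print(f"{violation.severity}: line {violation.line_number} "
          f"[{violation.rule_id}] {violation.message}")
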