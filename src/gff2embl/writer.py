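"""EMBL flat-file rendering.

An entry is emitted as the ENA submission variant of the flat file: ID/AC
lines with the "XXX" pre-submission placeholders, PR/DE/KW/OS/OC metadata,
one reference block, the FH/FT feature table with its fixed column layout
(key at column 6, location and qualifiers at column 22), the SQ block with
base-composition counts and 60-residue lines, and the "//" terminator.
Every emitted line is at most 80 characters and output is byte-deterministic:
no timestamps, no locale-dependent formatting.
"""

from __future__ import annotations

import gzip as _gzip
from dataclasses import dataclass, field
from pathlib import Path

from .feature_table import (DefinitionTables, EmblFeature, load_definitions,
                            render_location)
from .gff3 import GenomeSequence

__all__ = [
    "EmblEntry",
    "EntryMetadata",
    "Reference",
    "MAX_LINE",
    "TOPOLOGIES",
    "DATA_CLASSES",
    "DIVISIONS",
    "render_header",
    "render_feature_table",
    "render_sequence",
    "write_entry",
    "write_entries",
]

MAX_LINE = 80
FT_QUAL_COLUMN = 21  # 0-based; qualifier/location text starts at column 22

TOPOLOGIES = {"linear", "circular"}
DATA_CLASSES = {"STD", "WGS", "CON", "TSA", "EST", "GSS", "HTC", "HTG", "PAT", "SET"}
DIVISIONS = {"PHG", "ENV", "FUN", "HUM", "INV", "MAM", "VRT", "MUS", "PLN",
             "PRO", "ROD", "SYN", "TGN", "UNC", "VRL", "XXX"}


@dataclass
class Reference:
    authors: list[str] = field(default_factory=list)
    title: str = ""
    location: str = "Submitted to the INSDC."


@dataclass
class EntryMetadata:
    """Submission metadata ENA requires that a GFF3 file cannot carry."""

    organism: str = ""
    project_id: str = ""
    description: str = ""
    locus_tag_prefix: str = ""
    topology: str = "linear"
    molecule_type: str = "genomic DNA"
    data_class: str = "STD"
    taxonomic_division: str = "UNC"
    accession: str = "XXX"
    lineage: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    references: list[Reference] = field(default_factory=list)
    transl_table: int = 1
    strain: str = ""


@dataclass
class EmblEntry:
    """One sequence's complete flat-file content."""

    metadata: EntryMetadata
    sequence: GenomeSequence
    features: list[EmblFeature] = field(default_factory=list)


def _wrap(prefix: str, text: str, sep: str = " ") -> list[str]:
    """Wrap ``text`` into lines "prefix + chunk" of at most MAX_LINE chars.

    Breaks at ``sep`` boundaries when possible, hard-breaks unbroken tokens.
    """
    width = MAX_LINE - len(prefix)
    lines: list[str] = []
    remaining = text
    while len(remaining) > width:
        if sep == " ":
            cut = remaining.rfind(" ", 1, width + 1)
            if cut <= 0:
                chunk, remaining = remaining[:width], remaining[width:]
            else:
                chunk, remaining = remaining[:cut], remaining[cut + 1:]
        else:  # keep the separator (e.g. the comma of a join) at end of line
            cut = remaining.rfind(sep, 1, width)
            if cut <= 0:
                chunk, remaining = remaining[:width], remaining[width:]
            else:
                chunk, remaining = remaining[:cut + 1], remaining[cut + 1:]
        lines.append(prefix + chunk)
    lines.append(prefix + remaining)
    return lines


def _wrap_words(code: str, text: str) -> list[str]:
    prefix = f"{code}   "
    width = MAX_LINE - len(prefix)
    lines = []
    current = ""
    for word in text.split():
        candidate = f"{current} {word}".strip()
        if len(candidate) > width and current:
            lines.append(prefix + current)
            current = word
        else:
            current = candidate
    lines.append(prefix + current)
    return lines


def render_header(meta: EntryMetadata, seq_length: int, entry_name: str) -> list[str]:
    """Render the metadata header lines for one entry.

    The accession and sequence-version slots carry the literal "XXX"
    placeholder that ENA expects before accessioning.
    """
    lines: list[str] = []
    lines.append(f"ID   {meta.accession}; {meta.accession}; {meta.topology}; "
                 f"{meta.molecule_type}; {meta.accession}; "
                 f"{meta.taxonomic_division}; {seq_length} BP.")
    lines.append("XX")
    lines.append(f"AC   {meta.accession};")
    lines.append("XX")
    lines.append(f"AC * _{entry_name}")
    lines.append("XX")
    if meta.project_id:
        lines.append(f"PR   Project:{meta.project_id};")
        lines.append("XX")
    if meta.description:
        lines.extend(_wrap_words("DE", meta.description))
        lines.append("XX")
    keywords = "; ".join(meta.keywords) + "." if meta.keywords else "."
    lines.extend(_wrap_words("KW", keywords))
    lines.append("XX")
    organism = meta.organism + (f" (strain {meta.strain})" if meta.strain else "")
    lines.extend(_wrap_words("OS", organism))
    lineage = "; ".join(meta.lineage) + "." if meta.lineage else "unclassified sequences."
    lines.extend(_wrap_words("OC", lineage))
    lines.append("XX")
    references = meta.references or [Reference()]
    for i, ref in enumerate(references, start=1):
        lines.append(f"RN   [{i}]")
        lines.append(f"RP   1-{seq_length}")
        if ref.authors:
            lines.extend(_wrap_words("RA", ", ".join(ref.authors) + ";"))
        if ref.title:
            lines.extend(_wrap_words("RT", f'"{ref.title}";'))
        else:
            lines.append("RT   ;")
        lines.extend(_wrap_words("RL", ref.location or "Submitted to the INSDC."))
        lines.append("XX")
    return lines


def _render_qualifier(name: str, value: str | None,
                      defs: DefinitionTables) -> list[str]:
    prefix = "FT" + " " * (FT_QUAL_COLUMN - 2)
    qdef = defs.qualifiers.get(name)
    fmt = qdef.value_format if qdef is not None else "quoted-text"
    if value is None or fmt == "none":
        return [prefix + f"/{name}"]
    if fmt in ("integer", "unquoted-token"):
        return _wrap(prefix, f"/{name}={value}")
    escaped = value.replace('"', '""')
    return _wrap(prefix, f'/{name}="{escaped}"')


def render_feature_table(features: list[EmblFeature],
                         defs: DefinitionTables | None = None) -> list[str]:
    """Render the FH header and one FT block per feature.

    Keys sit left-justified at column 6 in a 16-character field; location
    expressions and qualifiers start at column 22. Long locations break only
    after commas; long quoted values break at spaces where possible.
    """
    defs = defs or load_definitions()
    lines = ["FH   Key             Location/Qualifiers", "FH"]
    key_prefix = "FT   "
    cont_prefix = "FT" + " " * (FT_QUAL_COLUMN - 2)
    for feature in features:
        location = render_location(feature.location)
        loc_lines = _wrap(cont_prefix, location, sep=",")
        first = key_prefix + feature.key.ljust(FT_QUAL_COLUMN - len(key_prefix)) \
            + loc_lines[0][FT_QUAL_COLUMN:]
        lines.append(first)
        lines.extend(loc_lines[1:])
        for name, value in feature.qualifiers:
            lines.extend(_render_qualifier(name, value, defs))
    return lines


def render_sequence(seq: GenomeSequence) -> list[str]:
    """Render the SQ block: composition header plus 60-residue data lines.

    Residues are emitted lower-case in six space-separated groups of ten,
    with the cumulative residue count right-justified so every data line is
    exactly 80 characters wide.
    """
    residues = seq.residues.lower()
    n = len(residues)
    counts = {base: residues.count(base) for base in "acgt"}
    other = n - sum(counts.values())
    lines = [f"SQ   Sequence {n} BP; {counts['a']} A; {counts['c']} C; "
             f"{counts['g']} G; {counts['t']} T; {other} other;"]
    for offset in range(0, n, 60):
        chunk = residues[offset:offset + 60]
        groups = [chunk[i:i + 10] for i in range(0, len(chunk), 10)]
        body = " ".join(groups)
        lines.append("     " + body.ljust(66) + str(offset + len(chunk)).rjust(9))
    return lines


def write_entry(entry: EmblEntry, defs: DefinitionTables | None = None) -> str:
    """Render one entry to flat-file text, terminator included."""
    lines = render_header(entry.metadata, len(entry.sequence), entry.sequence.id)
    lines.extend(render_feature_table(entry.features, defs))
    lines.append("XX")
    lines.extend(render_sequence(entry.sequence))
    lines.append("//")
    return "\n".join(lines) + "\n"


def write_entries(entries: list[EmblEntry], out: str | Path | None = None,
                  gzip: bool = False, defs: DefinitionTables | None = None) -> str:
    """Render entries in order; optionally write to ``out`` (gzipped on demand)."""
    text = "".join(write_entry(entry, defs) for entry in entries)
    if out is not None:
        path = Path(out)
        if gzip:
            # fileobj + fixed mtime keep the compressed bytes deterministic
            # (no filename or timestamp in the gzip header)
            with open(path, "wb") as raw, \
                    _gzip.GzipFile(filename="", fileobj=raw, mode="wb",
                                   mtime=0) as fh:
                fh.write(text.encode())
        else:
            path.write_text(text)
    return text
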