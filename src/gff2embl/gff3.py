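"""Tolerant GFF3 reading: records, attribute multimaps and feature hierarchies.

Annotation tools emit many dialects of GFF3. This parser accepts any of them:
structurally broken lines are reported as warnings (with line numbers) and
skipped rather than aborting the run, unless strict mode promotes warnings to
errors. Coordinates stay 1-based inclusive throughout, as in both GFF3 and the
INSDC feature table, so no conversion arithmetic exists anywhere downstream.
"""

from __future__ import annotations

import re
import urllib.parse
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "AnnotationRecord",
    "FeatureTree",
    "GenomeSequence",
    "Gff3Error",
    "GffDocument",
    "parse_attributes",
    "parse_gff3",
    "resolve_hierarchy",
]

VALID_STRANDS = {"+", "-", ".", "?"}

# GFF3 reserves these characters inside attribute values; they are
# percent-encoded on output and decoded on input.
_ENCODE_VALUE = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "\t": "%09",
                 "%": "%25"}
# Feature types whose lines must carry a phase (coding segments).
_CODING_TYPES = {"cds"}


class Gff3Error(ValueError):
    """Unrecoverable problem with a GFF3 document (e.g. no features at all)."""


@dataclass
class AnnotationRecord:
    """One parsed 9-column GFF3 line.

    ``attributes`` is an ordered multimap (tag -> list of values); both tag
    order and value order follow the source text.
    """

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    score: str | None
    strand: str
    phase: int | None
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def feature_id(self) -> str | None:
        values = self.attributes.get("ID")
        return values[0] if values else None

    @property
    def parents(self) -> list[str]:
        return list(self.attributes.get("Parent", []))

    def to_gff3_line(self) -> str:
        """Serialize back to a tab-separated 9-column line (round-trip safe)."""
        attrs = ";".join(
            f"{tag}=" + ",".join(_encode_value(v) for v in values)
            for tag, values in self.attributes.items()
        ) or "."
        return "\t".join([
            self.seqid, self.source, self.ftype, str(self.start),
            str(self.end), self.score if self.score is not None else ".",
            self.strand, str(self.phase) if self.phase is not None else ".",
            attrs,
        ])


@dataclass
class FeatureTree:
    """A feature and its ID/Parent descendants.

    Multi-line features (several GFF3 lines sharing one ID, e.g. a spliced
    CDS) collapse into a single node; ``segments`` holds every line's
    (start, end) sorted by start, and ``segment_phases`` the matching phase
    column values.
    """

    record: AnnotationRecord
    children: list["FeatureTree"] = field(default_factory=list)
    segments: list[tuple[int, int]] = field(default_factory=list)
    segment_phases: list[int | None] = field(default_factory=list)
    segment_strands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            self.segments = [(self.record.start, self.record.end)]
            self.segment_phases = [self.record.phase]
            self.segment_strands = [self.record.strand]

    @property
    def span(self) -> tuple[int, int]:
        return self.segments[0][0], self.segments[-1][1]

    def walk(self) -> Iterable["FeatureTree"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class GenomeSequence:
    """A named nucleotide sequence (IUPAC alphabet, case preserved as given)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GffDocument:
    """Everything read from one GFF3 file."""

    records: dict[str, list[AnnotationRecord]]
    sequences: list[GenomeSequence]
    warnings: list[str]

    def all_records(self) -> list[AnnotationRecord]:
        return [r for recs in self.records.values() for r in recs]


def _encode_value(value: str) -> str:
    return "".join(_ENCODE_VALUE.get(ch, ch) for ch in value)


def parse_attributes(col9: str) -> tuple[dict[str, list[str]], list[str]]:
    """Parse GFF3 column 9 into an ordered tag -> values multimap.

    Tags split on ";", values on ","; percent-escapes are decoded in values.
    A bare "." yields an empty multimap. Tokens without "=" yield a warning
    and are skipped. Returns (multimap, warnings).
    """
    attributes: dict[str, list[str]] = {}
    warnings: list[str] = []
    col9 = col9.strip()
    if col9 in (".", ""):
        return attributes, warnings
    for token in col9.split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" not in token:
            warnings.append(f"attribute token without '=' skipped: {token!r}")
            continue
        tag, _, raw = token.partition("=")
        values = [urllib.parse.unquote(v) for v in raw.split(",")]
        attributes.setdefault(tag, []).extend(values)
    return attributes, warnings


def _parse_fasta_block(lines: list[str], warnings: list[str]) -> list[GenomeSequence]:
    sequences: list[GenomeSequence] = []
    current_id: str | None = None
    chunks: list[str] = []
    for line in lines:
        line = line.rstrip()
        if line.startswith(">"):
            if current_id is not None:
                if chunks:
                    sequences.append(GenomeSequence(current_id, "".join(chunks)))
                else:
                    warnings.append(f"embedded FASTA record {current_id!r} has no residues")
            current_id = line[1:].split()[0] if line[1:].split() else ""
            chunks = []
        elif current_id is not None:
            chunks.append(line.strip())
    if current_id is not None:
        if chunks:
            sequences.append(GenomeSequence(current_id, "".join(chunks)))
        else:
            warnings.append(f"embedded FASTA record {current_id!r} has no residues")
    return sequences


def parse_gff3(text: str, strict: bool = False) -> GffDocument:
    """Parse a GFF3 document into per-seqid records plus embedded FASTA.

    Malformed data lines produce warnings naming the line number and are
    skipped. If the document contains data lines but none parse, a
    :class:`Gff3Error` is raised; a directive/comment-only document parses to
    an empty record set. With ``strict=True`` every warning is an error.
    """
    records: dict[str, list[AnnotationRecord]] = {}
    warnings: list[str] = []
    fasta_lines: list[str] = []
    in_fasta = False
    saw_data_line = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        if in_fasta:
            fasta_lines.append(line)
            continue
        stripped = line.rstrip("\n")
        if stripped.startswith("##FASTA"):
            in_fasta = True
            continue
        if not stripped.strip() or stripped.startswith("#"):
            continue
        saw_data_line = True
        fields = stripped.split("\t")
        if len(fields) != 9:
            warnings.append(f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}; line skipped")
            continue
        seqid, source, ftype, start_s, end_s, score, strand, phase_s, col9 = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            warnings.append(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}; line skipped")
            continue
        if start > end:
            warnings.append(f"line {lineno}: start {start} > end {end}; line skipped")
            continue
        if strand not in VALID_STRANDS:
            warnings.append(f"line {lineno}: invalid strand {strand!r}; line skipped")
            continue
        phase: int | None
        if phase_s == ".":
            phase = None
        else:
            try:
                phase = int(phase_s)
            except ValueError:
                warnings.append(f"line {lineno}: invalid phase {phase_s!r}; treated as absent")
                phase = None
            else:
                if phase not in (0, 1, 2):
                    warnings.append(f"line {lineno}: phase {phase} outside 0..2; treated as absent")
                    phase = None
        if phase is None and ftype.lower() in _CODING_TYPES:
            warnings.append(f"line {lineno}: coding feature {ftype!r} without phase")
        attributes, attr_warnings = parse_attributes(col9)
        warnings.extend(f"line {lineno}: {w}" for w in attr_warnings)
        record = AnnotationRecord(
            seqid=seqid, source=source, ftype=ftype, start=start, end=end,
            score=None if score == "." else score, strand=strand, phase=phase,
            attributes=attributes,
        )
        records.setdefault(seqid, []).append(record)

    sequences = _parse_fasta_block(fasta_lines, warnings) if fasta_lines else []
    if saw_data_line and not any(records.values()):
        raise Gff3Error("no features found: every data line failed to parse")
    if strict and warnings:
        raise Gff3Error("strict mode: " + "; ".join(warnings))
    return GffDocument(records=records, sequences=sequences, warnings=warnings)


def _sort_key(node: FeatureTree) -> tuple:
    return (node.span[0], node.span[1], node.record.ftype,
            node.record.feature_id or "")


def resolve_hierarchy(records: list[AnnotationRecord]) -> tuple[dict[str, list[FeatureTree]], list[str]]:
    """Link records into ID/Parent trees, one root list per seqid.

    Lines sharing an ID (within one seqid) merge into one multi-segment node.
    A Parent pointing at no known ID keeps the record as a root with a
    warning. Circular Parent chains raise :class:`Gff3Error` naming the IDs.
    Output ordering is deterministic and independent of input record order.
    """
    warnings: list[str] = []
    nodes_by_key: dict[tuple[str, str], FeatureTree] = {}
    anonymous: list[FeatureTree] = []
    id_seqids: dict[str, set[str]] = {}

    for record in records:
        fid = record.feature_id
        if fid is None:
            anonymous.append(FeatureTree(record=record))
            continue
        id_seqids.setdefault(fid, set()).add(record.seqid)
        key = (record.seqid, fid)
        node = nodes_by_key.get(key)
        if node is None:
            nodes_by_key[key] = FeatureTree(record=record)
        else:
            if record.ftype != node.record.ftype or record.strand != node.record.strand:
                warnings.append(
                    f"ID {fid!r} reused across differing type/strand "
                    f"({node.record.ftype}/{node.record.strand} vs "
                    f"{record.ftype}/{record.strand}); merged anyway")
            node.segments.append((record.start, record.end))
            node.segment_phases.append(record.phase)
            node.segment_strands.append(record.strand)

    for fid, seqids in id_seqids.items():
        if len(seqids) > 1:
            warnings.append(f"ID {fid!r} appears on multiple seqids "
                            f"({', '.join(sorted(seqids))}); treated as distinct features")

    for node in nodes_by_key.values():
        order = sorted(range(len(node.segments)), key=lambda i: node.segments[i])
        node.segments = [node.segments[i] for i in order]
        node.segment_phases = [node.segment_phases[i] for i in order]
        node.segment_strands = [node.segment_strands[i] for i in order]

    roots: dict[str, list[FeatureTree]] = {}
    parent_of: dict[tuple[str, str], tuple[str, str]] = {}
    for key, node in nodes_by_key.items():
        seqid = node.record.seqid
        parent_ids = node.record.parents
        attached = False
        for pid in parent_ids:
            parent = nodes_by_key.get((seqid, pid))
            if parent is not None and parent is not node:
                parent.children.append(node)
                parent_of[key] = (seqid, pid)
                attached = True
                break
            if parent is None:
                warnings.append(f"feature {node.record.feature_id!r} references "
                                f"unknown Parent {pid!r}; kept as a root")
        if not attached:
            roots.setdefault(seqid, []).append(node)
        if len(parent_ids) > 1:
            warnings.append(f"feature {node.record.feature_id!r} lists multiple "
                            f"parents; attached to the first known one")
    for node in anonymous:
        seqid = node.record.seqid
        pid = node.record.parents[0] if node.record.parents else None
        parent = nodes_by_key.get((seqid, pid)) if pid else None
        if parent is not None:
            parent.children.append(node)
        else:
            if pid:
                warnings.append(f"feature of type {node.record.ftype!r} references "
                                f"unknown Parent {pid!r}; kept as a root")
            roots.setdefault(seqid, []).append(node)

    # cycle check: follow parent links from every node
    for key in nodes_by_key:
        seen: list[tuple[str, str]] = []
        cursor: tuple[str, str] | None = key
        while cursor is not None:
            if cursor in seen:
                cycle = [k[1] for k in seen[seen.index(cursor):]]
                raise Gff3Error("circular Parent chain: " + " -> ".join(cycle + [cycle[0]]))
            seen.append(cursor)
            cursor = parent_of.get(cursor)

    for seqid_roots in roots.values():
        seqid_roots.sort(key=_sort_key)
    for node in nodes_by_key.values():
        node.children.sort(key=_sort_key)
    return roots, warnings


def read_fasta(text: str) -> list[GenomeSequence]:
    """Read FASTA text into GenomeSequences via Biopython, order preserved."""
    from io import StringIO

    from Bio import SeqIO

    sequences = [GenomeSequence(rec.id, str(rec.seq))
                 for rec in SeqIO.parse(StringIO(text), "fasta")]
    seen: set[str] = set()
    for seq in sequences:
        if seq.id in seen:
            raise ValueError(f"duplicate FASTA id {seq.id!r}")
        seen.add(seq.id)
    return sequences
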