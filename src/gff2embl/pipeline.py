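"""End-to-end conversion: GFF3 + FASTA + metadata -> EMBL flat file.

Walks each feature hierarchy, applies the vocabulary-mapping rules, builds
feature-table entries (CDS joins with codon_start, mRNA spans from exon
children, locus_tag assignment in genomic order) and emits one entry per
input sequence, the mandatory source feature first. Skipped or removed terms
never abort the run; they are tallied in the ConversionReport and the
accounting identity written + skipped + removed = candidates holds on every
run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .feature_table import (DefinitionTables, EmblFeature, build_location,
                            compute_codon_start, load_definitions)
from .gff3 import (FeatureTree, GenomeSequence, parse_gff3, read_fasta,
                   resolve_hierarchy)
from .mapping import (Mapped, MappingRuleSet, Removed, Skipped, Unknown,
                      load_default_rules, translate_attribute,
                      translate_feature_type)
from .writer import (DATA_CLASSES, DIVISIONS, TOPOLOGIES, EmblEntry,
                     EntryMetadata, write_entries)

__all__ = [
    "ConversionError",
    "ConversionReport",
    "assign_locus_tags",
    "build_embl_features",
    "check_metadata",
    "convert",
]

# Feature keys that carry the assigned locus_tag qualifier.
_LOCUS_TAG_KEYS = {"gene", "mRNA", "CDS", "tRNA", "rRNA", "ncRNA", "tmRNA",
                   "misc_RNA"}


class ConversionError(ValueError):
    """Unrecoverable conversion problem (bad metadata, missing sequence...)."""


@dataclass
class ConversionReport:
    """Accounting of one conversion run."""

    entries_written: int = 0
    features_written: int = 0
    features_skipped_unknown: dict[str, int] = field(default_factory=dict)
    features_removed_by_rule: dict[str, int] = field(default_factory=dict)
    attributes_skipped: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def candidates(self) -> int:
        """Total mapped-candidate features encountered (tree nodes + sources)."""
        return (self.features_written
                + sum(self.features_skipped_unknown.values())
                + sum(self.features_removed_by_rule.values()))

    def warn_once(self, message: str) -> None:
        if message not in self.warnings:
            self.warnings.append(message)


_METADATA_FLAGS = {
    "organism": "--species",
    "project_id": "--project_id",
    "description": "--description",
    "locus_tag_prefix": "--locus_tag",
    "topology": "--topology",
    "molecule_type": "--molecule_type",
    "data_class": "--data_class",
    "taxonomic_division": "--division",
}

_MOLECULE_TYPES = {"genomic DNA", "genomic RNA", "mRNA", "tRNA", "rRNA",
                   "other RNA", "other DNA", "transcribed RNA", "viral cRNA",
                   "unassigned DNA", "unassigned RNA"}


def check_metadata(meta: EntryMetadata) -> list[str]:
    """Report missing or invalid mandatory metadata, naming the fixing flag.

    Returns an empty list when the metadata is submission-ready; never raises.
    """
    findings: list[str] = []
    for attr in ("organism", "project_id", "description", "locus_tag_prefix"):
        if not getattr(meta, attr):
            findings.append(f"{attr}: required, set with {_METADATA_FLAGS[attr]}")
    for attr, allowed in (("topology", TOPOLOGIES),
                          ("molecule_type", _MOLECULE_TYPES),
                          ("data_class", DATA_CLASSES),
                          ("taxonomic_division", DIVISIONS)):
        value = getattr(meta, attr)
        if not value:
            findings.append(f"{attr}: required, set with {_METADATA_FLAGS[attr]}")
        elif value not in allowed:
            findings.append(f"{attr}: invalid value {value!r}, expected one of "
                            f"{{{', '.join(sorted(allowed))}}} "
                            f"(set with {_METADATA_FLAGS[attr]})")
    return findings


def assign_locus_tags(trees_by_seqid: dict[str, list[FeatureTree]], prefix: str,
                      width: int = 5, increment: int = 1) -> dict[int, str]:
    """Assign locus_tags to top-level features in ascending genomic order.

    Numbering runs across all seqids (in input order) without resetting.
    Roots already carrying a locus_tag attribute keep it verbatim and do not
    consume a counter value. Returns a map id(node) -> tag.
    """
    if not prefix:
        raise ValueError("locus_tag prefix must be non-empty")
    tags: dict[int, str] = {}
    counter = increment
    for roots in trees_by_seqid.values():
        for node in sorted(roots, key=lambda n: n.span):
            existing = node.record.attributes.get("locus_tag")
            if existing:
                tags[id(node)] = existing[0]
                continue
            tags[id(node)] = f"{prefix}_{counter:0{width}d}"
            counter += increment
    return tags


def _qualifiers_from_record(node: FeatureTree, rules: MappingRuleSet,
                            defs: DefinitionTables,
                            report: ConversionReport) -> list[tuple[str, str | None]]:
    qualifiers: list[tuple[str, str | None]] = []
    for tag, values in node.record.attributes.items():
        outcome = translate_attribute(tag, values, rules, defs)
        if outcome is Skipped:
            report.attributes_skipped[tag] = report.attributes_skipped.get(tag, 0) + 1
            report.warn_once(f"attribute tag {tag!r} matches no qualifier "
                             f"mapping and no EMBL qualifier; skipped")
        elif outcome is Removed:
            continue
        else:
            for name, value in outcome:
                qdef = defs.qualifiers.get(name)
                if qdef is not None and qdef.value_format == "none":
                    qualifiers.append((name, None))
                else:
                    qualifiers.append((name, value))
    # columns 2 (source) and 6 (score) flow through the "other" table
    for pseudo_tag, raw in (("source", node.record.source),
                            ("score", node.record.score)):
        if raw in (None, "", "."):
            continue
        outcome = translate_attribute(pseudo_tag, [raw], rules, defs, column=True)
        if outcome in (Skipped, Removed):
            continue
        qualifiers.extend(outcome)
    return qualifiers


def _dedupe(qualifiers: list[tuple[str, str | None]]) -> list[tuple[str, str | None]]:
    seen: set[tuple[str, str | None]] = set()
    out = []
    for pair in qualifiers:
        if pair not in seen:
            seen.add(pair)
            out.append(pair)
    return out


def build_embl_features(tree: FeatureTree, rules: MappingRuleSet,
                        defs: DefinitionTables | None = None,
                        locus_tag: str | None = None,
                        report: ConversionReport | None = None) -> list[EmblFeature]:
    """Translate one feature hierarchy into EMBL features.

    Every node is mapped independently (removal is per-node, never
    per-subtree). A node mapping to the CDS key renders its merged same-ID
    segments as one join with a computed codon_start; a node with exon
    children takes the join of their extents as its location, otherwise its
    own span. The assigned ``locus_tag`` attaches to gene- and
    transcript/CDS-level features that do not already carry one.
    """
    defs = defs or load_definitions()
    report = report if report is not None else ConversionReport()
    features: list[EmblFeature] = []
    for node in tree.walk():
        ftype = node.record.ftype
        outcome = translate_feature_type(ftype, rules, defs)
        if outcome is Removed:
            report.features_removed_by_rule[ftype] = \
                report.features_removed_by_rule.get(ftype, 0) + 1
            continue
        if outcome is Unknown:
            report.features_skipped_unknown[ftype] = \
                report.features_skipped_unknown.get(ftype, 0) + 1
            report.warn_once(f"feature type {ftype!r} matches no feature "
                             f"mapping and no EMBL feature key; skipped")
            continue
        key = outcome.key
        strand = node.record.strand
        if strand in (".", "?") and ftype.casefold() == "cds":
            report.warn_once(f"coding feature {node.record.feature_id!r} is "
                             f"unstranded; rendered without complement")
        if key == "CDS":
            if len(set(node.segment_strands)) > 1:
                raise ConversionError(
                    f"CDS {node.record.feature_id!r} has segments on mixed strands")
            segments = node.segments
            codon_start, cs_warnings = compute_codon_start(
                segments, strand, node.segment_phases)
            for w in cs_warnings:
                report.warn_once(f"CDS {node.record.feature_id!r}: {w}")
        else:
            exon_children = [c for c in node.children
                             if c.record.ftype.casefold() == "exon"]
            if exon_children:
                segments = sorted(seg for c in exon_children for seg in c.segments)
            else:
                # multi-line features sharing an ID render as a join, like CDS
                segments = node.segments
            codon_start = None
        feature = EmblFeature(key=key, location=build_location(segments, strand))
        qualifiers = _qualifiers_from_record(node, rules, defs, report)
        if locus_tag and key in _LOCUS_TAG_KEYS \
                and all(name != "locus_tag" for name, _ in qualifiers):
            qualifiers.insert(0, ("locus_tag", locus_tag))
        if codon_start is not None:
            qualifiers.append(("codon_start", str(codon_start)))
        feature.qualifiers = _dedupe(qualifiers)
        features.append(feature)
        report.features_written += 1
    return features


def _make_source_feature(seq: GenomeSequence, meta: EntryMetadata) -> EmblFeature:
    feature = EmblFeature(key="source", location=build_location([(1, len(seq))]))
    feature.add_qualifier("organism", meta.organism)
    feature.add_qualifier("mol_type", meta.molecule_type)
    if meta.strain:
        feature.add_qualifier("strain", meta.strain)
    return feature


def convert(gff3_text: str, fasta_text: str,
            rules: MappingRuleSet | None = None,
            meta: EntryMetadata | None = None,
            defs: DefinitionTables | None = None,
            strict: bool = False) -> tuple[str, ConversionReport]:
    """Convert a GFF3 document and its genome FASTA to EMBL flat-file text.

    One entry is emitted per FASTA sequence (in FASTA order), each opening
    with a source feature spanning the whole sequence. Sequences without
    features become source-only entries; a GFF3 seqid absent from the FASTA
    is an error. Returns (flat-file text, report); skipped vocabulary never
    fails the run.
    """
    defs = defs or load_definitions()
    rules = rules or load_default_rules(defs)
    meta = meta or EntryMetadata()

    findings = check_metadata(meta)
    if findings:
        raise ConversionError("metadata incomplete:\n  " + "\n  ".join(findings))

    report = ConversionReport()
    document = parse_gff3(gff3_text, strict=strict)
    report.warnings.extend(document.warnings)

    sequences = read_fasta(fasta_text) if fasta_text.strip() else []
    if not sequences and document.sequences:
        sequences = document.sequences
    elif document.sequences and sequences:
        report.warn_once("GFF3 contains an embedded ##FASTA block; the "
                         "external FASTA takes precedence")
    if not sequences:
        raise ConversionError("no sequences provided (FASTA empty and no ##FASTA block)")

    known = {seq.id for seq in sequences}
    missing = sorted(set(document.records) - known)
    if missing:
        raise ConversionError(
            "GFF3 references seqids absent from the FASTA: " + ", ".join(missing))

    trees_by_seqid, tree_warnings = resolve_hierarchy(document.all_records())
    report.warnings.extend(tree_warnings)
    if strict and (document.warnings or tree_warnings):
        raise ConversionError("strict mode: " + "; ".join(report.warnings))

    locus_tags = assign_locus_tags(trees_by_seqid, meta.locus_tag_prefix)

    entries: list[EmblEntry] = []
    for seq in sequences:
        features = [_make_source_feature(seq, meta)]
        report.features_written += 1
        for root in sorted(trees_by_seqid.get(seq.id, []), key=lambda n: n.span):
            tag = locus_tags.get(id(root))
            features.extend(build_embl_features(root, rules, defs,
                                                locus_tag=tag, report=report))
        for feature in features:
            if feature.location.end > len(seq):
                report.warn_once(
                    f"feature {feature.key} at {feature.location.start}.."
                    f"{feature.location.end} exceeds sequence {seq.id!r} "
                    f"length {len(seq)}")
        entries.append(EmblEntry(metadata=meta, sequence=seq,
                                 features=_sorted_features(features)))
        report.entries_written += 1
    text = write_entries(entries, defs=defs)
    return text, report


def _sorted_features(features: list[EmblFeature]) -> list[EmblFeature]:
    """Source first, the rest by leftmost genomic coordinate (stable)."""
    source = [f for f in features if f.key == "source"]
    rest = [f for f in features if f.key != "source"]
    rest.sort(key=lambda f: f.location.start)  # stable: gene before its children
    return source + rest
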