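"""Deterministic synthetic GFF3 + FASTA inputs in four annotation-tool dialects.

Each flavour profile caricatures the attribute conventions of a widely used
annotation tool — Maker (ID/Parent/Name plus ``_AED``-style extras and exon
features), Prokka (single-exon prokaryotic genes with locus_tag, product and
inference tags), Augustus (bare ``g1``/``g1.t1`` identifiers, multi-line CDS,
no exon features) and Eugene (ID/Parent with UTR features and Dbxref tags).
Profiles are built from the tools' documented output conventions, not
captured real outputs, so the repository ships no third-party data.

Generated gene models have 1–4 exons on either strand; CDS phases follow the
GFF3 phase recurrence along the translation direction, so an independent
phase walker reproduces them exactly. Sequences are uniform random A/C/G/T
with no biological signal (CDS translatability is deliberately out of scope).
All output is a pure function of (flavour, n_genes, seq_length, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

__all__ = ["FLAVOURS", "FlavourProfile", "generate_annotation", "next_phase"]


@dataclass(frozen=True)
class FlavourProfile:
    name: str
    seqid: str
    source_value: str
    transcript_type: str  # GFF3 term used for the transcript level
    emit_exons: bool
    emit_utrs: bool


FLAVOURS = {
    "maker": FlavourProfile("maker", "scaffold_1", "maker", "mRNA",
                            emit_exons=True, emit_utrs=False),
    "prokka": FlavourProfile("prokka", "contig_1", "Prokka", "mRNA",
                             emit_exons=False, emit_utrs=False),
    "augustus": FlavourProfile("augustus", "chr1", "AUGUSTUS", "transcript",
                               emit_exons=False, emit_utrs=False),
    "eugene": FlavourProfile("eugene", "chrom1", "EuGene", "mRNA",
                             emit_exons=True, emit_utrs=True),
}

_PRODUCTS = ["hypothetical protein", "DNA polymerase III subunit alpha",
             "ABC transporter permease", "50S ribosomal protein L3",
             "two-component sensor histidine kinase"]


def next_phase(prev_phase: int, prev_length: int) -> int:
    """GFF3 phase of the next CDS segment along the translation direction.

    The phase counts bases to skip at the segment start to reach the first
    complete codon: after a segment that consumed ``prev_length - prev_phase``
    coding bases, the leftover ``(prev_length - prev_phase) mod 3`` bases need
    ``(3 - leftover) mod 3`` partners from the next segment.
    """
    leftover = (prev_length - prev_phase) % 3
    return (3 - leftover) % 3


def _phases_for(segments: list[tuple[int, int]], strand: str) -> list[int]:
    """Phases per genomic-order segment, walking in translation order."""
    order = range(len(segments)) if strand == "+" else range(len(segments) - 1, -1, -1)
    phases = [0] * len(segments)
    phase = 0
    for idx in order:
        phases[idx] = phase
        phase = next_phase(phase, segments[idx][1] - segments[idx][0] + 1)
    return phases


def _attrs(pairs: list[tuple[str, str]]) -> str:
    return ";".join(f"{tag}={value}" for tag, value in pairs)


def _gene_model(rng: random.Random, start: int, profile: FlavourProfile):
    """Exon/CDS geometry for one gene, anchored at ``start``."""
    n_exons = 1 if profile.name == "prokka" else rng.randint(1, 4)
    exons: list[tuple[int, int]] = []
    cursor = start
    for _ in range(n_exons):
        length = rng.randint(120, 300)
        exons.append((cursor, cursor + length - 1))
        cursor = cursor + length - 1 + rng.randint(40, 100) + 1
    utr5 = rng.randint(10, 30) if profile.emit_utrs else 0
    utr3 = rng.randint(10, 30) if profile.emit_utrs else 0
    cds_start = exons[0][0] + utr5
    cds_end = exons[-1][1] - utr3
    cds = [(max(s, cds_start), min(e, cds_end)) for s, e in exons
           if e >= cds_start and s <= cds_end]
    total = sum(e - s + 1 for s, e in cds)
    trim = total % 3
    if trim:  # keep the coding length a whole number of codons
        s, e = cds[-1]
        cds[-1] = (s, e - trim)
        cds_end -= trim
    strand = rng.choice("+-")
    return exons, cds, cds_start, cds_end, strand


def generate_annotation(flavour: str, n_genes: int, seq_length: int,
                        seed: int) -> tuple[str, str]:
    """Generate one (GFF3 text, FASTA text) pair for the given flavour.

    Deterministic for a given argument tuple. Genes are packed left to right
    without overlap; if they do not fit in ``seq_length`` a ValueError is
    raised rather than producing an inconsistent file.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    profile = FLAVOURS.get(flavour)
    if profile is None:
        raise ValueError(f"unknown flavour {flavour!r}; "
                         f"choose from {', '.join(sorted(FLAVOURS))}")
    rng = random.Random(seed)
    seqid = profile.seqid
    lines = ["##gff-version 3", f"##sequence-region {seqid} 1 {seq_length}"]
    cursor = rng.randint(100, 200)
    for i in range(1, n_genes + 1):
        exons, cds, cds_start, cds_end, strand = _gene_model(rng, cursor, profile)
        gene_span = (exons[0][0], exons[-1][1])
        if gene_span[1] > seq_length - 50:
            raise ValueError(
                f"infeasible packing: gene {i} ends at {gene_span[1]} but the "
                f"sequence is only {seq_length} bases long")
        phases = _phases_for(cds, strand)
        lines.extend(_render_gene(profile, rng, i, seqid, strand, gene_span,
                                  exons, cds, cds_start, cds_end, phases))
        cursor = gene_span[1] + rng.randint(200, 500)
    sequence = "".join(rng.choice("acgt") for _ in range(seq_length))
    fasta_lines = [f">{seqid}"]
    fasta_lines.extend(sequence[i:i + 60] for i in range(0, seq_length, 60))
    return "\n".join(lines) + "\n", "\n".join(fasta_lines) + "\n"


def _render_gene(profile, rng, i, seqid, strand, gene_span, exons, cds,
                 cds_start, cds_end, phases) -> list[str]:
    src = profile.source_value
    ttype = profile.transcript_type
    out: list[str] = []

    def row(ftype, start, end, attrs, score=".", phase="."):
        out.append("\t".join([seqid, src, ftype, str(start), str(end),
                              score, strand, phase, attrs]))

    if profile.name == "maker":
        gid, tid = f"GENE_{i}", f"GENE_{i}-mRNA-1"
        row("gene", *gene_span, _attrs([("ID", gid), ("Name", f"gene{i}")]))
        row(ttype, *gene_span, _attrs([
            ("ID", tid), ("Parent", gid), ("Name", f"gene{i}-mRNA-1"),
            ("_AED", f"{rng.randint(0, 99) / 100:.2f}"),
            ("_eAED", f"{rng.randint(0, 99) / 100:.2f}"),
            ("_QI", "0|1|1|1|1|1|1|0|100")]))
        for j, (s, e) in enumerate(exons, start=1):
            row("exon", s, e, _attrs([("ID", f"{tid}:exon:{j}"), ("Parent", tid)]))
        for (s, e), ph in zip(cds, phases):
            row("CDS", s, e, _attrs([("ID", f"{tid}:cds"), ("Parent", tid)]),
                phase=str(ph))
    elif profile.name == "prokka":
        gid, tid, cid = f"PROKKA_g{i}", f"PROKKA_t{i}", f"PROKKA_c{i}"
        gene_attrs = [("ID", gid), ("gene", f"yfg{chr(64 + (i - 1) % 26 + 1)}")]
        if i % 2 == 1:  # odd genes carry a pre-assigned locus_tag
            gene_attrs.append(("locus_tag", f"PROKKA_{i:05d}"))
        row("gene", *gene_span, _attrs(gene_attrs))
        row(ttype, *gene_span, _attrs([("ID", tid), ("Parent", gid)]))
        for (s, e), ph in zip(cds, phases):
            row("CDS", s, e, _attrs([
                ("ID", cid), ("Parent", tid),
                ("product", rng.choice(_PRODUCTS)),
                ("inference", "ab initio prediction:Prodigal:2.6")]),
                phase=str(ph))
    elif profile.name == "augustus":
        gid, tid = f"g{i}", f"g{i}.t1"
        row("gene", *gene_span, _attrs([("ID", gid)]))
        row(ttype, *gene_span, _attrs([("ID", tid), ("Parent", gid)]),
            score=f"{rng.randint(50, 100) / 100:.2f}")
        for (s, e), ph in zip(cds, phases):
            row("CDS", s, e, _attrs([("ID", f"{tid}.cds"), ("Parent", tid)]),
                phase=str(ph))
    else:  # eugene
        gid, tid = f"EuGene_gene_{i}", f"EuGene_mRNA_{i}"
        row("gene", *gene_span, _attrs([
            ("ID", gid), ("Name", f"eg{i}"),
            ("Note", f"predicted gene model {i}")]))
        mrna_attrs = [("ID", tid), ("Parent", gid)]
        if rng.random() < 0.5:
            mrna_attrs.append(("Dbxref", f"GO:{rng.randint(1, 9999999):07d}"))
        row(ttype, *gene_span, _attrs(mrna_attrs))
        for j, (s, e) in enumerate(exons, start=1):
            row("exon", s, e, _attrs([("ID", f"{tid}.exon{j}"), ("Parent", tid)]))
        left_utr = (gene_span[0], cds_start - 1)
        right_utr = (cds_end + 1, gene_span[1])
        left_type = "five_prime_UTR" if strand == "+" else "three_prime_UTR"
        right_type = "three_prime_UTR" if strand == "+" else "five_prime_UTR"
        if left_utr[0] <= left_utr[1]:
            row(left_type, *left_utr,
                _attrs([("ID", f"{tid}.utr_l"), ("Parent", tid)]))
        if right_utr[0] <= right_utr[1]:
            row(right_type, *right_utr,
                _attrs([("ID", f"{tid}.utr_r"), ("Parent", tid)]))
        for (s, e), ph in zip(cds, phases):
            row("CDS", s, e, _attrs([("ID", f"{tid}.cds"), ("Parent", tid)]),
                phase=str(ph))
    return out
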