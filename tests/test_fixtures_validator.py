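"""Synthetic fixture generation and structural flat-file validation."""

import pytest

from gff2embl.fixtures import FLAVOURS, generate_annotation, next_phase
from gff2embl.gff3 import parse_gff3, resolve_hierarchy
from gff2embl.pipeline import convert
from gff2embl.validator import validate_flat_file


def phase_walker_oracle(segments, strand):
    """Recompute CDS phases by walking codons along the translation direction.

    Starts with a complete codon at the translation start (phase 0) and
    carries the codon remainder across segments, independently of the
    generator's own recurrence.
    """
    order = segments if strand == "+" else segments[::-1]
    phases = []
    carried = 0  # bases of the current codon still owed from the last segment
    for start, end in order:
        phase = (3 - carried) % 3
        phases.append(phase)
        length = end - start + 1
        carried = (carried + length) % 3
    return phases if strand == "+" else phases[::-1]


class TestGenerator:
    def test_determinism(self):
        a = generate_annotation("prokka", 5, 20000, 42)
        b = generate_annotation("prokka", 5, 20000, 42)
        assert a == b

    def test_seed_changes_output(self):
        assert generate_annotation("prokka", 5, 20000, 1) != \
            generate_annotation("prokka", 5, 20000, 2)

    def test_zero_genes_degenerate(self):
        gff, fasta = generate_annotation("maker", 0, 1000, 1)
        assert all(line.startswith("#") for line in gff.splitlines())
        assert fasta.count(">") == 1
        assert sum(len(l) for l in fasta.splitlines()[1:]) == 1000

    def test_infeasible_packing_is_an_error(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_annotation("maker", 50, 2000, 1)

    def test_unknown_flavour_is_an_error(self):
        with pytest.raises(ValueError, match="flavour"):
            generate_annotation("snap", 1, 10000, 1)

    @pytest.mark.parametrize("flavour", sorted(FLAVOURS))
    def test_phases_satisfy_codon_walk(self, flavour):
        gff, _ = generate_annotation(flavour, 3, 15000, 7)
        doc = parse_gff3(gff, strict=True)
        roots, _ = resolve_hierarchy(doc.all_records())
        checked = 0
        for seq_roots in roots.values():
            for root in seq_roots:
                for node in root.walk():
                    if node.record.ftype != "CDS":
                        continue
                    expected = phase_walker_oracle(node.segments,
                                                   node.record.strand)
                    assert node.segment_phases == expected
                    checked += 1
        assert checked == 3

    @pytest.mark.parametrize("flavour", sorted(FLAVOURS))
    def test_generated_gff3_reparses_strict_without_warnings(self, flavour):
        gff, _ = generate_annotation(flavour, 5, 20000, 13)
        doc = parse_gff3(gff, strict=True)
        assert doc.warnings == []
        _, warnings = resolve_hierarchy(doc.all_records())
        assert warnings == []

    def test_next_phase_recurrence_matches_walker(self):
        # single chain of segments: recurrence == codon walker, all lengths
        for length in range(1, 10):
            for phase in (0, 1, 2):
                segs = [(1, length), (100, 100 + 6 - 1)]
                walked = phase_walker_oracle(segs, "+")
                if walked[0] == phase:
                    assert next_phase(phase, length) == walked[1]
                assert next_phase(phase, length) == \
                    (3 - ((length - phase) % 3)) % 3


class TestValidator:
    @pytest.fixture()
    def flat_text(self, meta):
        gff, fasta = generate_annotation("prokka", 3, 15000, 21)
        text, _ = convert(gff, fasta, meta=meta)
        return text

    def test_silence_on_converted_output(self, flat_text):
        assert validate_flat_file(flat_text) == []

    def test_missing_terminator(self, flat_text):
        broken = flat_text.rsplit("//", 1)[0]
        violations = validate_flat_file(broken)
        assert any(v.rule_id == "MISSING_TERMINATOR" and v.severity == "error"
                   for v in violations)

    def test_overlong_line_cited_by_number(self, flat_text):
        lines = flat_text.splitlines()
        idx = next(i for i, l in enumerate(lines) if l.startswith("FT   CDS"))
        lines[idx] = lines[idx] + "x" * (95 - len(lines[idx]))
        violations = validate_flat_file("\n".join(lines) + "\n")
        long_hits = [v for v in violations if v.rule_id == "LINE_LENGTH"]
        assert len(long_hits) == 1 and long_hits[0].line_number == idx + 1

    @pytest.mark.parametrize("mutate,rule_id", [
        (lambda l: l.replace("FT   gene", "QQ   gene", 1), "LINE_CODE"),
        (lambda l: l.replace("FT   gene            ",
                             "FT   not_a_key       ", 1), "UNKNOWN_KEY"),
        (lambda l: l.replace("/product=", "/produkt=", 1), "UNKNOWN_QUALIFIER"),
        (lambda l: l.replace("FT   source          1..15000",
                             "FT   source          1..25000", 1), "COORD_RANGE"),
        (lambda l: l.replace(" A;", " A!;", 1), "SQ_COUNTS"),
    ])
    def test_single_line_corruptions_are_flagged(self, flat_text, mutate, rule_id):
        mutated = mutate(flat_text)
        assert mutated != flat_text, "mutation did not apply"
        violations = validate_flat_file(mutated)
        assert any(v.rule_id == rule_id for v in violations), (
            rule_id, violations[:5])

    def test_wrong_sq_composition_count(self, flat_text):
        import re

        mutated = re.sub(r"(\d+) A;", lambda m: f"{int(m.group(1)) + 1} A;",
                         flat_text, count=1)
        violations = validate_flat_file(mutated)
        assert any(v.rule_id == "SQ_COUNTS" for v in violations)

    def test_source_must_be_first(self, flat_text):
        lines = flat_text.splitlines()
        src = next(i for i, l in enumerate(lines) if l.startswith("FT   source"))
        # drop the source key line and its qualifiers
        end = src + 1
        while lines[end][5:21].strip() == "":
            end += 1
        del lines[src:end]
        violations = validate_flat_file("\n".join(lines) + "\n")
        assert any(v.rule_id == "SOURCE_FIRST" for v in violations)

    def test_out_of_order_lines(self, flat_text):
        lines = flat_text.splitlines()
        # move the ID line after the feature table header
        idline = lines.pop(0)
        fh = next(i for i, l in enumerate(lines) if l.startswith("FH"))
        lines.insert(fh + 1, idline)
        violations = validate_flat_file("\n".join(lines) + "\n")
        assert any(v.rule_id == "LINE_ORDER" for v in violations)
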