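"""Definition tables, location algebra and codon_start against oracles."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gff2embl.feature_table import (EmblFeature, Location, LocationError,
                                    build_location, check_qualifier_legality,
                                    compute_codon_start, parse_location,
                                    render_location)


class TestDefinitionTables:
    def test_cardinality(self, defs):
        assert len(defs.feature_keys) == 52
        assert len(defs.qualifiers) == 98

    def test_source_mandatory_qualifiers(self, defs):
        mandatory = set(defs.feature_keys["source"].mandatory_qualifiers)
        assert {"organism", "mol_type"} <= mandatory

    def test_every_listed_qualifier_is_defined(self, defs):
        for key_def in defs.feature_keys.values():
            for name in key_def.legal_qualifiers:
                assert name in defs.qualifiers

    def test_valueless_formats(self, defs):
        assert defs.qualifiers["pseudo"].value_format == "none"
        assert defs.qualifiers["codon_start"].value_format == "integer"


class TestBuildLocation:
    def test_simple_forward(self):
        loc = build_location([(100, 200)], "+")
        assert loc == Location([(100, 200)], complement=False)

    def test_segments_sorted_and_complement(self):
        loc = build_location([(300, 400), (100, 200)], "-")
        assert loc.segments == [(100, 200), (300, 400)] and loc.complement

    def test_overlap_is_an_error(self):
        with pytest.raises(LocationError, match="overlap"):
            build_location([(100, 200), (150, 250)], "+")

    def test_inverted_segment_is_an_error(self):
        with pytest.raises(LocationError):
            build_location([(20, 10)], "+")


class TestRenderLocation:
    @pytest.mark.parametrize("loc,expected", [
        (Location([(100, 200)]), "100..200"),
        (Location([(100, 200), (300, 400)], complement=True),
         "complement(join(100..200,300..400))"),
        (Location([(1, 200)], partial5=True), "<1..200"),
        (Location([(1, 200)], partial3=True), "1..>200"),
        (Location([(7, 7)]), "7..7"),
        (Location([(1, 200)], complement=True, partial5=True), "complement(1..>200)"),
        (Location([(1, 200)], complement=True, partial3=True), "complement(<1..200)"),
        (Location([(10, 20), (30, 40)], partial5=True, partial3=True),
         "join(<10..20,30..>40)"),
    ])
    def test_grammar(self, loc, expected):
        assert render_location(loc) == expected

    @settings(max_examples=300, deadline=None)
    @given(data=st.data())
    def test_render_parse_round_trip(self, data):
        n = data.draw(st.integers(1, 5))
        bounds = sorted(data.draw(
            st.lists(st.integers(1, 10 ** 7), min_size=2 * n, max_size=2 * n,
                     unique=True)))
        segments = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n)]
        loc = Location(segments,
                       complement=data.draw(st.booleans()),
                       partial5=data.draw(st.booleans()),
                       partial3=data.draw(st.booleans()))
        text = render_location(loc)
        assert parse_location(text) == loc
        assert render_location(parse_location(text)) == text


def oracle_codon_start(segments, strand, phases):
    """Brute-force oracle: walk the coding bases in translation order.

    Lays out every genomic position of the CDS in the order the ribosome
    reads them, skips the declared phase of the first translated segment,
    and reports 1 + the number of skipped bases, i.e. the position within
    the first translated segment where the first complete codon begins.
    """
    order = sorted(range(len(segments)), key=lambda i: segments[i][0],
                   reverse=(strand == "-"))
    first = order[0]
    positions = []
    for idx in order:
        span = range(segments[idx][0], segments[idx][1] + 1)
        positions.extend((idx, p) for p in
                         (reversed(span) if strand == "-" else span))
    skip = phases[first] or 0
    walked = positions[skip:]
    assert walked and walked[0][0] == first
    skipped_in_first = sum(1 for idx, _ in positions[:skip] if idx == first)
    return skipped_in_first + 1


class TestCodonStart:
    @pytest.mark.parametrize("strand", "+-")
    @pytest.mark.parametrize("phase", [0, 1, 2])
    @pytest.mark.parametrize("reverse_input", [False, True])
    def test_truth_table_against_oracle(self, strand, phase, reverse_input):
        segments = [(100, 200), (300, 400)]
        # the declared phase sits on the first *translated* segment
        phases = [phase, 1] if strand == "+" else [1, phase]
        if reverse_input:  # input segment order must not matter
            segments, phases = segments[::-1], phases[::-1]
        result, warnings = compute_codon_start(segments, strand, phases)
        assert result == oracle_codon_start(segments, strand, phases)
        assert result == phase + 1
        assert warnings == []

    def test_absent_phase_assumes_zero_with_warning(self):
        result, warnings = compute_codon_start([(10, 20)], "+", [None])
        assert result == 1 and len(warnings) == 1

    def test_minus_strand_uses_rightmost_segment(self):
        result, _ = compute_codon_start([(100, 200), (300, 400)], "-", [2, 1])
        assert result == 2

    def test_plus_strand_phase_two(self):
        result, _ = compute_codon_start([(100, 200)], "+", [2])
        assert result == 3

    def test_illegal_phase_raises(self):
        with pytest.raises(ValueError):
            compute_codon_start([(1, 10)], "+", [5])


class TestQualifierLegality:
    def test_complete_source_is_clean(self, defs):
        feature = EmblFeature("source", build_location([(1, 100)]),
                              [("organism", "E. coli"),
                               ("mol_type", "genomic DNA")])
        assert check_qualifier_legality(feature, defs) == []

    def test_organism_not_legal_on_cds(self, defs):
        assert "organism" not in defs.feature_keys["CDS"].legal_qualifiers
        feature = EmblFeature("CDS", build_location([(1, 99)]),
                              [("organism", "E. coli")])
        violations = check_qualifier_legality(feature, defs)
        assert len(violations) == 1 and "organism" in violations[0]

    def test_missing_mandatory_mol_type(self, defs):
        feature = EmblFeature("source", build_location([(1, 100)]),
                              [("organism", "E. coli")])
        violations = check_qualifier_legality(feature, defs)
        assert len(violations) == 1 and "mol_type" in violations[0]
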