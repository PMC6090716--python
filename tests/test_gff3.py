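"""GFF3 parsing, attribute multimaps and ID/Parent hierarchy resolution."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gff2embl.gff3 import (AnnotationRecord, Gff3Error, parse_attributes,
                           parse_gff3, resolve_hierarchy)


class TestParseAttributes:
    @pytest.mark.parametrize("col9,expected", [
        ("ID=gene1;Dbxref=GO:0005575,GO:0003674",
         {"ID": ["gene1"], "Dbxref": ["GO:0005575", "GO:0003674"]}),
        ("Note=a%2Cb", {"Note": ["a,b"]}),
        (".", {}),
        ("", {}),
        ("Note=a%3Bb%3Dc%26d", {"Note": ["a;b=c&d"]}),
    ])
    def test_grammar(self, col9, expected):
        attrs, warnings = parse_attributes(col9)
        assert attrs == expected
        assert warnings == []

    def test_token_without_equals_is_warned_and_skipped(self):
        attrs, warnings = parse_attributes("ID=g1;garbage;Name=x")
        assert attrs == {"ID": ["g1"], "Name": ["x"]}
        assert len(warnings) == 1 and "garbage" in warnings[0]

    def test_tag_and_value_order_preserved(self):
        attrs, _ = parse_attributes("z=1;a=2,3;m=4")
        assert list(attrs) == ["z", "a", "m"]
        assert attrs["a"] == ["2", "3"]


class TestParseGff3:
    def test_well_formed_file(self, tiny_gff3):
        doc = parse_gff3(tiny_gff3)
        assert sum(len(r) for r in doc.records.values()) == 6
        assert doc.sequences == []
        assert doc.warnings == []

    def test_malformed_line_warned_with_line_number(self):
        text = ("chr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=g1\n"
                "chr1\tsrc\tmRNA\t1\t10\t.\t+\t.\tID=m1;Parent=g1\n"
                "chr1\tsrc\texon\t1\t10\t.\t+\n"  # 8 columns
                "chr1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=c1;Parent=m1\n")
        doc = parse_gff3(text)
        assert sum(len(r) for r in doc.records.values()) == 3
        assert len(doc.warnings) == 1 and "line 3" in doc.warnings[0]

    def test_embedded_fasta_block(self):
        residues = "".join(random.Random(0).choice("acgt") for _ in range(120))
        text = ("chr9\tsrc\tgene\t1\t50\t.\t+\t.\tID=g1\n"
                "##FASTA\n>chr9\n" + residues[:60] + "\n" + residues[60:] + "\n")
        doc = parse_gff3(text)
        assert len(doc.sequences) == 1
        assert len(doc.sequences[0]) == 120
        assert doc.sequences[0].residues == residues

    def test_only_unparseable_data_lines_is_an_error(self):
        with pytest.raises(Gff3Error, match="no features"):
            parse_gff3("chr1\tonly\tfour\tcolumns\n")

    def test_directive_only_document_is_empty_not_an_error(self):
        doc = parse_gff3("##gff-version 3\n")
        assert doc.records == {} and doc.warnings == []

    def test_strict_mode_promotes_warnings(self):
        text = ("chr1\tsrc\tgene\t1\t10\t.\t+\t.\tID=g1\n"
                "chr1\tsrc\texon\t1\t10\t.\t+\n")
        with pytest.raises(Gff3Error, match="strict"):
            parse_gff3(text, strict=True)


class TestRoundTrip:
    tags = st.text(alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"),
                                          whitelist_characters="_"),
                   min_size=1, max_size=8)
    # edge whitespace is stripped by the tolerant parser, so keep values to
    # printable non-space text (GFF3 files never carry significant edge spaces)
    values = st.lists(
        st.text(alphabet=st.characters(blacklist_categories=("C", "Z")),
                min_size=1, max_size=12),
        min_size=1, max_size=3)

    @settings(max_examples=200, deadline=None)
    @given(attrs=st.dictionaries(tags, values, min_size=0, max_size=5),
           start=st.integers(1, 10000), length=st.integers(0, 500),
           strand=st.sampled_from("+-.?"),
           phase=st.sampled_from([None, 0, 1, 2]))
    def test_serialize_then_reparse_is_identity(self, attrs, start, length,
                                                strand, phase):
        record = AnnotationRecord("chr1", "toolX", "misc_feature", start,
                                  start + length, None, strand, phase,
                                  dict(attrs))
        doc = parse_gff3(record.to_gff3_line() + "\n")
        assert doc.warnings == []
        (reparsed,) = doc.all_records()
        assert reparsed == record


class TestResolveHierarchy:
    def test_three_level_tree_with_multisegment_cds(self, tiny_gff3):
        doc = parse_gff3(tiny_gff3)
        roots, warnings = resolve_hierarchy(doc.all_records())
        assert warnings == []
        assert list(roots) == ["chr1"] and len(roots["chr1"]) == 1
        gene = roots["chr1"][0]
        assert gene.record.ftype == "gene"
        (mrna,) = gene.children
        cds = [c for c in mrna.children if c.record.ftype == "CDS"]
        assert len(cds) == 1
        assert cds[0].segments == [(150, 400), (500, 850)]
        assert cds[0].segment_phases == [0, 1]

    def test_single_record_is_a_root(self):
        doc = parse_gff3("chr1\ts\tgene\t5\t10\t.\t+\t.\tID=g1\n")
        roots, warnings = resolve_hierarchy(doc.all_records())
        assert len(roots["chr1"]) == 1 and not roots["chr1"][0].children
        assert warnings == []

    def test_orphan_parent_becomes_root_with_warning(self):
        doc = parse_gff3("chr1\ts\tmRNA\t5\t10\t.\t+\t.\tID=m1;Parent=ghost\n")
        roots, warnings = resolve_hierarchy(doc.all_records())
        assert len(roots["chr1"]) == 1
        assert any("ghost" in w for w in warnings)

    def test_circular_parent_chain_is_an_error(self):
        text = ("chr1\ts\tmRNA\t1\t10\t.\t+\t.\tID=a;Parent=b\n"
                "chr1\ts\tmRNA\t1\t10\t.\t+\t.\tID=b;Parent=a\n")
        doc = parse_gff3(text)
        with pytest.raises(Gff3Error, match="circular"):
            resolve_hierarchy(doc.all_records())

    def test_same_id_on_different_seqids_kept_distinct(self):
        text = ("chr1\ts\tmatch\t1\t10\t.\t+\t.\tID=x\n"
                "chr2\ts\tmatch\t5\t20\t.\t+\t.\tID=x\n")
        doc = parse_gff3(text)
        roots, warnings = resolve_hierarchy(doc.all_records())
        assert len(roots["chr1"]) == 1 and len(roots["chr2"]) == 1
        assert any("multiple seqids" in w for w in warnings)

    def test_order_independence(self, tiny_gff3):
        doc = parse_gff3(tiny_gff3)
        records = doc.all_records()
        baseline, _ = resolve_hierarchy(records)

        def shape(roots):
            return [
                [(n.record.ftype, tuple(n.segments),
                  [(c.record.ftype, tuple(c.segments)) for c in n.walk()])
                 for n in seq_roots]
                for seq_roots in roots.values()
            ]

        rng = random.Random(7)
        for _ in range(10):
            shuffled = records[:]
            rng.shuffle(shuffled)
            roots, _ = resolve_hierarchy(shuffled)
            assert shape(roots) == shape(baseline)

    def test_node_multiset_matches_input_lines(self, tiny_gff3):
        doc = parse_gff3(tiny_gff3)
        roots, _ = resolve_hierarchy(doc.all_records())
        from_tree = sorted(
            (node.record.seqid, node.record.ftype, seg[0], seg[1])
            for seq_roots in roots.values() for root in seq_roots
            for node in root.walk() for seg in node.segments)
        from_lines = sorted((r.seqid, r.ftype, r.start, r.end)
                            for r in doc.all_records())
        assert from_tree == from_lines
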