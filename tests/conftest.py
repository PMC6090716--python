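import pytest
from hypothesis import settings

from gff2embl.feature_table import load_definitions

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")
from gff2embl.mapping import load_default_rules
from gff2embl.writer import EntryMetadata


@pytest.fixture(scope="session")
def defs():
    return load_definitions()


@pytest.fixture(scope="session")
def default_rules(defs):
    return load_default_rules(defs)


@pytest.fixture()
def meta():
    return EntryMetadata(
        organism="Escherichia coli",
        strain="K-12",
        project_id="PRJEB14359",
        description="whole genome shotgun assembly",
        locus_tag_prefix="TEST",
        taxonomic_division="PRO",
        lineage=["Bacteria", "Pseudomonadota", "Gammaproteobacteria",
                 "Enterobacterales", "Enterobacteriaceae", "Escherichia"],
        keywords=["WGS"],
    )


@pytest.fixture()
def tiny_gff3():
    return "\n".join([
        "##gff-version 3",
        "##sequence-region chr1 1 1200",
        "chr1\ttest\tgene\t100\t900\t.\t+\t.\tID=g1;Name=geneA",
        "chr1\ttest\tmRNA\t100\t900\t.\t+\t.\tID=m1;Parent=g1",
        "chr1\ttest\texon\t100\t400\t.\t+\t.\tID=e1;Parent=m1",
        "chr1\ttest\texon\t500\t900\t.\t+\t.\tID=e2;Parent=m1",
        "chr1\ttest\tCDS\t150\t400\t.\t+\t0\tID=c1;Parent=m1;product=widget",
        "chr1\ttest\tCDS\t500\t850\t.\t+\t1\tID=c1;Parent=m1;product=widget",
    ]) + "\n"


@pytest.fixture()
def tiny_fasta():
    seq = "acgt" * 300
    return ">chr1\n" + "\n".join(seq[i:i + 60] for i in range(0, len(seq), 60)) + "\n"
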