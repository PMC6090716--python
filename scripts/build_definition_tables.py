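"""One-off generator for the bundled INSDC definition tables.

Writes src/gff2embl/data/embl_feature_keys.json and embl_qualifiers.json.
Counts are asserted here (52 feature keys, 98 qualifiers) and again by tests.
"""
import json
from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "gff2embl" / "data"

# ---------------------------------------------------------------- qualifiers
# format: none | quoted-text | unquoted-token | integer
Q = {}


def q(name, fmt, definition):
    Q[name] = {"format": fmt, "definition": definition, "comment": ""}


q("allele", "quoted-text", "name of the allele for the given gene")
q("altitude", "quoted-text", "geographical altitude of the collection location")
q("anticodon", "unquoted-token", "location of the anticodon and the amino acid it codes for")
q("artificial_location", "quoted-text", "annotation is known to contain frameshifts or internal stops")
q("bio_material", "quoted-text", "identifier of a biological material collection")
q("bound_moiety", "quoted-text", "name of the molecule or complex that binds the feature")
q("cell_line", "quoted-text", "cell line from which the sequence was obtained")
q("cell_type", "quoted-text", "cell type from which the sequence was obtained")
q("chromosome", "quoted-text", "chromosome from which the sequence was obtained")
q("citation", "unquoted-token", "reference to a citation listed in the entry reference block")
q("clone", "quoted-text", "clone from which the sequence was obtained")
q("clone_lib", "quoted-text", "clone library from which the sequence was obtained")
q("codon_start", "integer", "offset (1, 2 or 3) of the first complete codon in the coding feature")
q("collected_by", "quoted-text", "name of the person who collected the specimen")
q("collection_date", "quoted-text", "date the specimen was collected")
q("compare", "unquoted-token", "reference to an existing sequence record for comparison")
q("country", "quoted-text", "locality of isolation, starting with the country name")
q("cultivar", "quoted-text", "cultivated plant variety from which the sequence was obtained")
q("culture_collection", "quoted-text", "identifier of a live microbial or viral culture collection")
q("db_xref", "quoted-text", "cross-reference to an external database entry")
q("dev_stage", "quoted-text", "developmental stage of the source organism")
q("direction", "unquoted-token", "direction of DNA replication (left, right or both)")
q("EC_number", "quoted-text", "Enzyme Commission number of the enzyme product")
q("ecotype", "quoted-text", "ecotype of the organism")
q("environmental_sample", "none", "sequence obtained directly from an environmental sample")
q("estimated_length", "unquoted-token", "estimated length of a sequence gap")
q("exception", "quoted-text", "translation differs from conceptual translation for a stated reason")
q("experiment", "quoted-text", "experimental evidence supporting the feature")
q("focus", "none", "source feature that the entry description and taxonomy refer to")
q("frequency", "quoted-text", "frequency of occurrence of the feature")
q("function", "quoted-text", "function attributed to the sequence")
q("gap_type", "quoted-text", "type of assembly gap")
q("gene", "quoted-text", "symbol of the gene corresponding to the feature")
q("gene_synonym", "quoted-text", "synonym of the gene symbol")
q("germline", "none", "sequence is unrearranged DNA")
q("haplogroup", "quoted-text", "haplogroup of the organism")
q("haplotype", "quoted-text", "haplotype of the organism")
q("host", "quoted-text", "natural host of the organism from which the sequence was obtained")
q("identified_by", "quoted-text", "name of the expert who identified the specimen")
q("inference", "quoted-text", "structured description of non-experimental evidence")
q("isolate", "quoted-text", "individual isolate from which the sequence was obtained")
q("isolation_source", "quoted-text", "physical or environmental source of the isolate")
q("lab_host", "quoted-text", "laboratory host used to propagate the organism")
q("lat_lon", "quoted-text", "latitude and longitude of the collection location")
q("linkage_evidence", "quoted-text", "evidence linking the sequence on either side of an assembly gap")
q("locus_tag", "quoted-text", "systematic submission-wide gene identifier")
q("macronuclear", "none", "macronuclear DNA of a ciliate")
q("map", "quoted-text", "genomic map position of the feature")
q("mating_type", "quoted-text", "mating type of the organism")
q("mobile_element_type", "quoted-text", "type and name of the mobile element")
q("mod_base", "unquoted-token", "abbreviation of the modified nucleotide base")
q("mol_type", "quoted-text", "in vivo molecule type of the sequence")
q("ncRNA_class", "quoted-text", "class of the non-coding RNA")
q("note", "quoted-text", "any comment or additional information")
q("number", "unquoted-token", "number of the exon or intron within the gene")
q("old_locus_tag", "quoted-text", "locus_tag used in a previous submission")
q("operon", "quoted-text", "name of the operon the feature belongs to")
q("organelle", "quoted-text", "organelle membrane-bound intracellular structure of origin")
q("organism", "quoted-text", "scientific name of the source organism")
q("partial", "none", "feature is incomplete (deprecated in favour of location partials)")
q("PCR_conditions", "quoted-text", "PCR reaction conditions")
q("PCR_primers", "quoted-text", "PCR primers used to amplify the sequence")
q("phenotype", "quoted-text", "phenotype conferred by the feature")
q("plasmid", "quoted-text", "plasmid from which the sequence was obtained")
q("pop_variant", "quoted-text", "population variant of the organism")
q("product", "quoted-text", "name of the product of the feature")
q("protein_id", "quoted-text", "protein accession of the coding-sequence product")
q("proviral", "none", "sequence is integrated into the genome of another organism")
q("pseudo", "none", "non-functional copy of the feature (legacy marker)")
q("pseudogene", "quoted-text", "type of pseudogene")
q("rearranged", "none", "sequence is rearranged DNA")
q("regulatory_class", "quoted-text", "class of the regulatory element")
q("replace", "quoted-text", "sequence to replace the span of the feature")
q("ribosomal_slippage", "none", "translation involves ribosomal slippage")
q("rpt_family", "quoted-text", "family of the repeated sequence")
q("rpt_type", "unquoted-token", "organisation of the repeat")
q("rpt_unit_range", "unquoted-token", "range of the repeat unit within the sequence")
q("rpt_unit_seq", "quoted-text", "sequence of the repeat unit")
q("satellite", "quoted-text", "satellite DNA identifier")
q("segment", "quoted-text", "name of the viral or phage segment")
q("serotype", "quoted-text", "serotype of the organism")
q("serovar", "quoted-text", "serovar of the organism")
q("sex", "quoted-text", "sex of the organism")
q("specimen_voucher", "quoted-text", "identifier of the specimen in a curated collection")
q("standard_name", "quoted-text", "accepted standard name of the feature")
q("strain", "quoted-text", "strain from which the sequence was obtained")
q("sub_clone", "quoted-text", "sub-clone from which the sequence was obtained")
q("sub_species", "quoted-text", "subspecies of the organism")
q("sub_strain", "quoted-text", "sub-strain of the organism")
q("tag_peptide", "unquoted-token", "location of the tag peptide coding sequence of a tmRNA")
q("tissue_lib", "quoted-text", "tissue library from which the sequence was obtained")
q("tissue_type", "quoted-text", "tissue type from which the sequence was obtained")
q("transgenic", "none", "source of a transgenic organism carrying foreign DNA")
q("translation", "quoted-text", "conceptual amino-acid translation of the coding sequence")
q("transl_except", "unquoted-token", "translation exception at a stated location")
q("transl_table", "integer", "genetic code table used for translation")
q("trans_splicing", "none", "feature is produced by trans-splicing")
q("variety", "quoted-text", "variety of the organism")

assert len(Q) == 98, len(Q)

# -------------------------------------------------------------- feature keys
COMMON = ["allele", "citation", "db_xref", "experiment", "function", "gene",
          "gene_synonym", "inference", "locus_tag", "map", "note",
          "old_locus_tag", "standard_name"]
RNAISH = COMMON + ["operon", "product", "pseudo", "pseudogene", "trans_splicing"]
SEGLIKE = COMMON + ["product", "pseudo", "pseudogene"]

F = {}


def f(key, mandatory=(), optional=()):
    F[key] = {"mandatory": list(mandatory), "optional": list(optional)}


f("assembly_gap", ["estimated_length", "gap_type"], ["linkage_evidence"])
f("C_region", [], SEGLIKE)
f("CDS", [], COMMON + ["artificial_location", "codon_start", "EC_number",
                       "exception", "number", "operon", "product",
                       "protein_id", "pseudo", "pseudogene",
                       "ribosomal_slippage", "translation", "transl_except",
                       "transl_table", "trans_splicing"])
f("centromere", [], COMMON)
f("D-loop", [], COMMON)
f("D_segment", [], SEGLIKE)
f("exon", [], COMMON + ["number", "pseudo", "pseudogene", "trans_splicing"])
f("gap", ["estimated_length"], ["experiment", "inference", "map", "note"])
f("gene", [], COMMON + ["operon", "phenotype", "product", "pseudo",
                        "pseudogene", "trans_splicing"])
f("iDNA", [], COMMON + ["number"])
f("intron", [], COMMON + ["number", "pseudo", "pseudogene", "trans_splicing"])
f("J_segment", [], SEGLIKE)
f("mat_peptide", [], COMMON + ["EC_number", "product", "pseudo", "pseudogene"])
f("misc_binding", ["bound_moiety"], COMMON)
f("misc_difference", [], COMMON + ["clone", "compare", "phenotype", "replace"])
f("misc_feature", [], COMMON + ["number", "phenotype", "product", "pseudo",
                                "pseudogene"])
f("misc_recomb", [], COMMON)
f("misc_RNA", [], RNAISH)
f("misc_structure", [], COMMON)
f("mobile_element", ["mobile_element_type"], COMMON + ["rpt_family",
                                                       "rpt_type"])
f("modified_base", ["mod_base"], COMMON + ["frequency"])
f("mRNA", [], RNAISH + ["artificial_location"])
f("ncRNA", ["ncRNA_class"], RNAISH)
f("N_region", [], SEGLIKE)
f("old_sequence", ["citation"], ["allele", "compare", "db_xref",
                                 "experiment", "gene", "gene_synonym",
                                 "inference", "locus_tag", "map", "note",
                                 "old_locus_tag", "replace"])
f("operon", ["operon"], COMMON + ["phenotype", "pseudo", "pseudogene"])
f("oriT", [], COMMON + ["bound_moiety", "direction", "rpt_family", "rpt_type",
                        "rpt_unit_range", "rpt_unit_seq"])
f("polyA_site", [], COMMON)
f("precursor_RNA", [], RNAISH)
f("prim_transcript", [], RNAISH)
f("primer_bind", [], COMMON + ["PCR_conditions"])
f("propeptide", [], COMMON + ["product", "pseudo", "pseudogene"])
f("protein_bind", ["bound_moiety"], COMMON + ["operon"])
f("regulatory", ["regulatory_class"], COMMON + ["bound_moiety", "operon",
                                                "phenotype", "pseudo",
                                                "pseudogene"])
f("repeat_region", [], COMMON + ["mobile_element_type", "rpt_family",
                                 "rpt_type", "rpt_unit_range", "rpt_unit_seq",
                                 "satellite"])
f("rep_origin", [], COMMON + ["direction"])
f("rRNA", [], RNAISH)
f("S_region", [], SEGLIKE)
f("sig_peptide", [], COMMON + ["product", "pseudo", "pseudogene"])
f("source", ["organism", "mol_type"],
  ["altitude", "bio_material", "cell_line", "cell_type", "chromosome",
   "citation", "clone", "clone_lib", "collected_by", "collection_date",
   "country", "cultivar", "culture_collection", "db_xref", "dev_stage",
   "ecotype", "environmental_sample", "focus", "germline", "haplogroup",
   "haplotype", "host", "identified_by", "isolate", "isolation_source",
   "lab_host", "lat_lon", "macronuclear", "map", "mating_type", "note",
   "organelle", "PCR_primers", "plasmid", "pop_variant", "proviral",
   "rearranged", "segment", "serotype", "serovar", "sex", "specimen_voucher",
   "strain", "sub_clone", "sub_species", "sub_strain", "tissue_lib",
   "tissue_type", "transgenic", "variety"])
f("stem_loop", [], COMMON + ["operon"])
f("STS", [], COMMON)
f("telomere", [], COMMON + ["rpt_type", "rpt_unit_range", "rpt_unit_seq"])
f("tmRNA", [], RNAISH + ["tag_peptide"])
f("transit_peptide", [], COMMON + ["product", "pseudo", "pseudogene"])
f("tRNA", [], RNAISH + ["anticodon"])
f("unsure", [], COMMON + ["compare", "replace"])
f("variation", [], COMMON + ["compare", "frequency", "phenotype", "product",
                             "replace"])
f("V_region", [], SEGLIKE)
f("V_segment", [], SEGLIKE)
f("3'UTR", [], COMMON + ["trans_splicing"])
f("5'UTR", [], COMMON + ["trans_splicing"])

assert len(F) == 52, len(F)
for key, d in F.items():
    for name in d["mandatory"] + d["optional"]:
        assert name in Q, (key, name)

DATA.mkdir(parents=True, exist_ok=True)
(DATA / "embl_feature_keys.json").write_text(json.dumps(F, indent=1) + "\n")
(DATA / "embl_qualifiers.json").write_text(json.dumps(Q, indent=1) + "\n")
print("feature keys:", len(F), "qualifiers:", len(Q))
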