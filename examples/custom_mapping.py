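"""Steer the conversion with user-edited JSON mapping tables.

Shows the three rule shapes: renaming a feature type to its EMBL feature
key, dropping a feature type with "remove", and mapping the GFF3 source
column to a note qualifier with a prefix. The same tables can be exported
with expose_translations() (or `gff2embl expose-translations DIR`), edited,
and passed back to the converter.
"""

from gff2embl import (load_definitions, load_rules, translate_attribute,
                      translate_feature_type)

defs = load_definitions()

rules = load_rules(
    feature_json='{"three_prime_UTR": {"target": "3\'UTR"}}',
    attribute_json='{"Dbxref": {"target": "db_xref"}}',
    other_json='{"source": {"target": "note", "prefix": "source:"}}',
    defs=defs,
)

print("three_prime_UTR ->", translate_feature_type("three_prime_UTR", rules, defs))
print("Dbxref=GO:0005575 ->",
      translate_attribute("Dbxref", ["GO:0005575"], rules, defs))
print("source column 'Prokka' ->",
      translate_attribute("source", ["Prokka"], rules, defs, column=True))

drop = load_rules('{"three_prime_UTR": {"remove": true}}', "{}", "{}", defs=defs)
print("with remove rule ->", translate_feature_type("three_prime_UTR", drop, defs))

# without any rule, terms that already are EMBL vocabulary pass through
empty = load_rules("{}", "{}", "{}", defs=defs)
print("CDS with no rules ->", translate_feature_type("CDS", empty, defs))
print("unknown term ->", translate_feature_type("protein_match", empty, defs))
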