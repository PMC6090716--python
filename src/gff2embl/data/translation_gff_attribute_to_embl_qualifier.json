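{
 "ID": {"remove": true},
 "Parent": {"remove": true},
 "Name": {"remove": true},
 "Alias": {"remove": true},
 "Target": {"remove": true},
 "Gap": {"remove": true},
 "Derives_from": {"remove": true},
 "Is_circular": {"remove": true},
 "Ontology_term": {"remove": true},
 "Dbxref": {"target": "db_xref"},
 "dbxref": {"target": "db_xref"},
 "Note": {"target": "note"},
 "note": {"target": "note"},
 "description": {"target": "note"},
 "product": {"target": "product"},
 "gene": {"target": "gene"},
 "locus_tag": {"target": "locus_tag"},
 "protein_id": {"target": "protein_id"},
 "inference": {"target": "inference"},
 "eC_number": {"target": "EC_number"},
 "ec_number": {"target": "EC_number"},
 "transl_table": {"target": "transl_table"},
 "_AED": {"remove": true},
 "_eAED": {"remove": true},
 "_QI": {"remove": true}
}
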