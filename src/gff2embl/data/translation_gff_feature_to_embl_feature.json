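{
 "gene": {"target": "gene"},
 "pseudogene": {"target": "gene"},
 "mRNA": {"target": "mRNA"},
 "transcript": {"target": "mRNA"},
 "CDS": {"target": "CDS"},
 "exon": {"remove": true},
 "intron": {"remove": true},
 "start_codon": {"remove": true},
 "stop_codon": {"remove": true},
 "three_prime_UTR": {"target": "3'UTR"},
 "five_prime_UTR": {"target": "5'UTR"},
 "tRNA": {"target": "tRNA"},
 "rRNA": {"target": "rRNA"},
 "ncRNA": {"target": "ncRNA"},
 "tmRNA": {"target": "tmRNA"},
 "misc_RNA": {"target": "misc_RNA"},
 "repeat_region": {"target": "repeat_region"},
 "region": {"remove": true},
 "chromosome": {"remove": true},
 "contig": {"remove": true},
 "scaffold": {"remove": true}
}
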