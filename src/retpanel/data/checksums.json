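{
 "table1_genes.tsv": "c3c95fe783879cc6bb8a00a130e523f98279da293bafb2718ad4dfb984016826",
 "table3_patients.tsv": "f2c1e638f5b9e5e3eb91205223c53ccd0dfd0612e00b114ff882231feba85b32"
}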