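n_loci,homology_families,selftarget_subtype,n_unique_acr_ids
42,AcrIF3,I-E,1
4,AcrIF6,I-E,1
2,AcrIF1,I-E,1
2,AcrIE3,I-F,1
6,AcrIIA2,I-B,1
1,AcrIIA3;AcrIIA2,I-B,1
1,AcrIIA4,I-B,1
1,AcrIE3;AcrIF4,I-C,1
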