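phylum,n_loci
Proteobacteria,456
Firmicutes,340
Actinobacteria,15
Bacteroidetes,3
Chloroflexi,1
Fusobacteria,1
Spirochaetes,1
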