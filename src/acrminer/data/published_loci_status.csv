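species,refseq_genome_id,locus,status
Listeria monocytogenes J0161,GCF_000168635,AcrIIA2-AcrIIA1,complete_and_selftarget
Listeria monocytogenes serotype 7 strain SLCC2482,GCF_000210795,AcrIIA2-AcrIIA3-AcrIIA1,complete_and_selftarget
Listeria monocytogenes J0161,GCF_000168635,AcrIIA4-AcrIIA1,complete_and_selftarget
Pseudomonas otitidis,GCF_900111835,AcrIE5-Aca1,complete_and_selftarget
Pseudomonas aeruginosa WH-SGI-V-07059,GCF_001450485,AcrIF4-AcrIE3-Aca1,no_selftarget_spacer
Haemophilus parainfluenzae,GCF_001053575,AcrIIC4-Aca2,no_selftarget_spacer
Pseudomonas citronellolis,GCF_001654435,AcrIE4-IF7-Aca1,no_selftarget_spacer
Pseudomonas aeruginosa strain C 1426,GCF_000412555,AcrIF11-Aca1,no_selftarget_spacer
Pseudomonas aeruginosa strain Jp54,GCF_003836565,AcrIF6-Aca1,no_selftarget_spacer
Vibrio parahaemolyticus,GCF_000736335,AcrIF9-Aca1,no_complete_crispr_cas
Shewanella xiamenensis,GCF_000712635,AcrIF10-Aca1,no_complete_crispr_cas
Neisseria meningitidis,GCF_001066195,AcrIIC1-Aca3,no_complete_crispr_cas
Neisseria meningitidis 992008,GCF_000724735,AcrIIC2-AcaIIC3-Aca3,no_complete_crispr_cas
Simonsiella muelleri ATCC 29453,GCF_000163775,AcrIIC5-Aca2,no_complete_crispr_cas
Pseudomonas aeruginosa strain S708_C14_RS,GCF_002136415,AcrIE6-Aca1,no_complete_crispr_cas
Pseudomonas aeruginosa strain 359,GCF_002312455,AcrIF12-Aca4,no_complete_crispr_cas
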