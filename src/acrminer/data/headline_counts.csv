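quantity,numerator,denominator
refseq_acr_homologs_with_aca,224,975
imgvr_acr_homologs_with_aca,165,2022
acriia7_acriia9_share_refseq,585,975
loci_with_acr_among_full_filter,367,508
loci_selftarget_among_acr_aca,376,1193
subtype_assignments_agreeing,317,376
ta_paired_loci,32,817
published_loci_complete_selftarget,4,16
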