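# Minimal subtype-defining cas gene sets used for the completeness check.
# One row per subtype: subtype <TAB> comma-joined mandatory gene names.
# This is an editable canonical simplification: completeness is a pure
# set-cover test against these names, not a re-annotation of cas genes.
I-B	cas1,cas2,cas3,cas4,cas5,cas6,cas7,cas8b
I-C	cas1,cas2,cas3,cas4,cas5,cas7,cas8c
I-D	cas1,cas2,cas3d,cas4,cas5,cas6,cas7,cas10d
I-E	cas1,cas2,cas3,cas5,cas6e,cas7,cas8e
I-F	cas1,cas2-3,cas5f,cas6f,cas7f,cas8f
II-A	cas9,cas1,cas2,csn2
II-C	cas9,cas1,cas2
III-A	cas1,cas2,cas6,cas10,csm2,csm3,csm4,csm5
III-B	cas6,cas10,cmr1,cmr3,cmr4,cmr5,cmr6
IV-A	csf1,csf2,csf3,dinG
V-A	cas12a,cas1,cas2,cas4
V-U4	c2c9
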