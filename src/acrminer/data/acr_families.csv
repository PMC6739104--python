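family
AcrIF1
AcrIF2
AcrIF3
AcrIF4
AcrIF5
AcrIF6
AcrIF7
AcrIF8
AcrIF9
AcrIF10
AcrIF11
AcrIF12
AcrIF13
AcrIF14
AcrIE1
AcrIE2
AcrIE3
AcrIE4
AcrIE5
AcrIE6
AcrIE7
AcrIE4-IF7
AcrIC1
AcrID1
AcrIIA1
AcrIIA2
AcrIIA3
AcrIIA4
AcrIIA5
AcrIIA6
AcrIIA7
AcrIIA8
AcrIIA9
AcrIIA10
AcrIIA11
AcrIIC1
AcrIIC2
AcrIIC3
AcrIIC4
AcrIIC5
AcrVA1
AcrVA2
AcrVA3
AcrVA4
AcrVA5
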